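# mlsupertree

Approximate maximum-likelihood supertree estimation from partially
overlapping input trees.

## The problem

A supertree amalgamates a collection of trees with partially overlapping
leaf sets — typically gene trees from a phylogenomic study, or published
phylogenies in a meta-analysis — into one tree on the union of their
taxa.  Most supertree methods in common use (MRP above all) are ad hoc;
this package implements a fully parametric alternative: each input tree
T′ on taxon set Υ is modelled as a subsample of the supertree T,
reconstructed with exponentially decaying topological error,

    P(T′ | T, Υ) = α · exp(−β · d(T′, T|Υ))

where T|Υ is the supertree pruned to the input tree's taxa and d is the
Robinson–Foulds symmetric difference on full splits.  The supertree's
log-likelihood is the sum over input trees, and the maximum-likelihood
supertree is the tree maximising it.  The normalising constant α in
principle depends on |Υ|, but for small β it is well approximated by
α = 1, which shifts every candidate's score equally and leaves all
rankings unchanged; β is likewise fixed at 1, so under the defaults the
total log-likelihood is exactly −Σᵢ dᵢ, and the ML supertree is a median
tree of the inputs under the RF metric.

The package provides:

- the likelihood itself (`score_supertree`, `tree_wise_log_likelihood`),
  with per-input-tree breakdowns;
- heuristic search (`run_search`): SPR hill climbing with four
  strategies (steepest ascent, first-improvement, radius-limited
  steepest ascent, greedy subtree sweep — the default), randomized
  greedy stepwise-addition starting trees, random restarts, and an
  exhaustive-enumeration oracle for ≤ 8 taxa;
- bootstrap support (`bootstrap_support_analysis`): tree-level
  resampling, per-replicate searches, majority-rule consensus and
  split-support annotation;
- hypothesis testing (`rank_hypotheses`, `winning_sites_test`): ranking
  of a-priori candidate supertrees, an exact two-sided sign test on
  per-input-tree fits, and export of the per-tree log-likelihood matrix
  in CONSEL's `.mt` format for KH/SH/AU tests (input trees play the role
  of sites);
- tree utilities: newick/NEXUS I/O, pruning, derooting/rerooting,
  polytomy resolution (random or reference-guided), taxon extraction,
  bootstrap file generation;
- a synthetic-data generator (`generate_inputs`) that simulates input
  trees under the model's own error process, for validation and
  benchmarking.

## Worked example

`examples/score_supertree.py` scores a six-taxon mammal supertree
against four quartet input trees:

```
per input tree (index, taxa, d, log-likelihood):
  0  4 taxa  d=0  lnL=+0.0
  1  4 taxa  d=2  lnL=-2.0
  2  4 taxa  d=0  lnL=+0.0
  3  4 taxa  d=2  lnL=-2.0
total log-likelihood: -4.0
```

Two input quartets match the supertree's restriction exactly (d = 0);
the other two each conflict in their single informative split, so the
pruned supertree and the input tree differ in two splits (d = 2) and
each contributes −2.  `examples/search_ml_supertree.py` then recovers a
known 7-taxon tree from 100 distortion-free subsamples:

```
best log-likelihood: 0.0 (0 means every input tree fits exactly)
topology recovered:  True
```

See also `examples/bootstrap_support.py` (support values) and
`examples/hypothesis_testing.py` (ranking, winning-sites, CONSEL
export).

## Command line

The same workflow is available from a shell:

```sh
mlsupertree ml   --input genetrees.nwk --strategy 4 --iterations 10 --seed 1 --out run
mlsupertree boot --input genetrees.nwk --replicates 20 --seed 1 --out boot
mlsupertree test --input genetrees.nwk --hypotheses hyps.nwk --out tests
mlsupertree util prune|deroot|reroot|resolve|convert|taxa|bootstrap-sets ...
```

`ml` writes the best tree (`run.best.nwk`), a per-input-tree score table
(`run.scores.tsv`) and a log with the seed and score trajectory; `boot`
writes the consensus and the support-annotated ML tree; `test` writes a
ranking table, winning-sites results and a CONSEL `.mt` matrix.  Every
stochastic command takes `--seed` and is byte-reproducible.

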