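# Methods

## Model

An input tree T′ on taxa Υ is treated as a subsample of a supertree T:
prune T to Υ, then allow reconstruction error that decays exponentially
with topological distance.  The probability of observing T′ is
P(T′ | T, Υ) = α·exp(−β·d), where d is the Robinson–Foulds symmetric
difference between T|Υ and T′, counted over non-trivial full splits in
both directions (the unhalved convention; two fully resolved,
entirely conflicting n-leaf trees are at distance 2(n−3)).  Input trees
are assumed independent, so the supertree's log-likelihood is the sum of
per-tree terms ln α − β·d.

Distances are computed on the unrooted view of both trees: the RF
symmetric difference is a function of split sets, and splits are an
unrooted notion, so rooting of inputs or candidates never affects a
score.  Branch lengths are carried through I/O but ignored throughout.

### Parameters

- **α > 0** (default 1): the per-tree normalising constant, which in
  principle counts trees at each distance and depends on |Υ|.  It is
  fixed at 1: for any fixed β, changing α shifts every candidate's total
  by |inputs|·ln α, so the argmax and all rankings are unchanged.  This
  invariance is asserted empirically in the tests.  The consequence is
  that reported values are *approximate* likelihoods, comparable across
  supertrees but not interpretable as calibrated probabilities.
- **β > 0** (default 1): the weight expressing the quantity and quality
  of the data behind the input trees; larger β penalises conflict more
  sharply.  A single global β is used (no per-tree weights).  β is a
  library-level parameter — useful for testing the score's linearity —
  but is deliberately absent from the CLI, which pins it to 1; the α = 1
  approximation is justified specifically in the small-β regime.

Under the defaults the total log-likelihood is exactly −Σ dᵢ with
integer dᵢ, so scores are exact integers and the ML supertree is a
median tree of the inputs in RF space.

Input trees with fewer than four taxa (or whose overlap with a partial
tree during stepwise addition is smaller) carry no informative splits:
they contribute ln α always and cannot influence the ranking.  They are
scored, flagged with a warning, and otherwise harmless.

## Search

The score surface over binary unrooted supertrees is a plateau-rich
integer landscape, so the search is strict-improvement hill climbing
with seeded random tie-breaking: lateral moves are never taken, which
guarantees termination without cycle detection; the cost is that
plateaus must be crossed by restarts rather than drift.  Restarts use
fresh stepwise-addition starting trees (taxa shuffled, each taxon
greedily inserted at the score-maximising edge, with both the growing
tree and the inputs restricted to their shared taxa — on the full tree
this scoring coincides with the ordinary one).  A user-supplied starting
tree is used for the first climb; polytomous starts are resolved at
random with a warning, since the SPR neighborhood is defined on binary
trees and the optimum over resolutions is never worse.

The SPR neighborhood prunes the subtree on either side of every edge
and regrafts it on every edge of the remaining tree, deduplicating
topologies by split set.  Four strategies span the thoroughness/speed
spectrum:

1. **steepest ascent** — full neighborhood each iteration, move to the
   best strict improvement;
2. **first-improvement** — accept the first strictly better neighbor in
   a shuffled order;
3. **radius-limited steepest ascent** — as 1, with regraft destinations
   within 3 edges of the pruning point (breadth-first distance from the
   edge created by the prune);
4. **greedy subtree sweep** (default) — one pass over prunable subtrees
   in random order, each immediately regrafted to its best destination
   if strictly improving.

One iteration is one neighborhood pass (1–3) or one sweep (4); the
search stops at `max_iterations` (default 10) or when an iteration
yields no improvement.  The shipped defaults (strategy 4, ten
iterations) reflect the fastest, least exhaustive configuration; the
validation suite uses strategy 1 with five restarts, which attains the
exhaustively verified optimum on essentially every small instance
tried.  `exhaustive_ml_supertree` enumerates all (2n−5)!! binary
unrooted topologies for n ≤ 8 and serves as the search's oracle.

## Bootstrap support

The resampling unit is the input tree (datasets of trees are
bootstrapped, not characters within alignments).  Each of the n_reps
replicates draws |inputs| trees with replacement, is searched with the
caller's configuration under a derived seed (base seed + 1 + replicate
index, for reproducible yet independent streams), and the replicate
optima are summarised two ways: a majority-rule consensus, and the
original ML tree annotated with each split's replicate frequency.
Consensus uses the strict ">" rule at the 50% threshold, so splits in
exactly half the trees are excluded and the retained splits are
pairwise compatible by construction; the threshold is exposed as a
parameter, and below 50 splits are inserted greedily in order of
decreasing frequency, skipping incompatibilities.  Support for any
split — including splits absent from the consensus — can be queried
from the recorded split frequencies.

## Hypothesis testing

Hypotheses are ranked by total log-likelihood with competition ranking
(ties share the smaller rank and are flagged).  The winning-sites test
is the classical sign test: each input tree votes for the hypothesis
with the strictly better tree-wise log-likelihood (under defaults, the
smaller RF distance), ties are excluded, and the p-value is the exact
two-sided binomial probability of a split at least as extreme under
Binomial(wins_a + wins_b, ½); an all-ties comparison gets p = 1 by
convention.  The test is defined pairwise, with an all-pairs wrapper.
KH/SH/AU tests are not reimplemented: the contract is a clean CONSEL
`.mt` matrix (header `#hypotheses #sites`, one row of per-input-tree
log-likelihoods per hypothesis, six-decimal fixed format, names in a
sidecar file) in which input trees act as sites, so CONSEL's RELL
bootstrap resamples trees.

## Synthetic data

The generator simulates exactly the process the likelihood assumes:
draw a uniform taxon subset of a size in `subset_size_range`, restrict
the true supertree to it, and apply k random NNI rearrangements with
k ~ Poisson(`distortion_rate`).  NNI (rather than SPR) edits are used so
the perturbation strength maps finely onto RF distance; a Poisson count
of single edits gives the exponential-like decay of tree probability in
d that the model posits.  The defaults — a 7-taxon truth, 100 input
trees of 4–7 taxa — mirror a small phylogenomic pruning protocol in
which a large gene-tree collection is restricted to a handful of focal
taxa.  What the generator does *not* emulate: systematic (shared) error
across gene trees, coalescent gene-tree/species-tree discordance,
alignment-level uncertainty, or taxon subsets correlated with topology.
Passing tests therefore demonstrate correctness of the machinery and
consistency under the model's own assumptions, not robustness to
model violation on real data.

## Numerical and representational choices

- Splits are canonically encoded as unordered pairs of frozen taxon
  sets; equality is orientation-free.  Scoring restricts the
  supertree's split set to each input tree's taxa instead of pruning
  tree structures (the two are provably equivalent; the literal
  prune-then-RF route is kept in `tree_wise_log_likelihood` and the two
  are cross-checked in the tests), making repeated scoring during
  search cheap.
- Score comparisons in the search use a 1e-12 tolerance; under the
  default model all totals are integers, so this is conservative.
- Newick dialect: unquoted labels exclude `( ) , : ;` and whitespace;
  single-quoted labels are unescaped.  Parse errors name the character
  offset; file-level errors name the line.  NEXUS TREES blocks (with
  TRANSLATE) are read and written via dendropy.
- A tree with a bifurcating root is treated as rooted, one with a
  multifurcating root as unrooted; deroot/reroot utilities convert
  between the two and conserve the unrooted split set exactly.
- Degenerate inputs: pruning to fewer than two shared taxa drops the
  tree with a warning in batch pruning and is an error for a single
  tree only when the intersection is empty; derooting needs ≥ 3 leaves;
  rerooting on a non-split outgroup is an error ("not monophyletic").

## Validation problem sizes

The test and acceptance workloads use 6–8-taxon instances with 20–100
input trees, sizes at which exhaustive enumeration (105–10395
topologies) provides a ground-truth oracle for every stochastic
component, and recovery/bootstrap experiments run 10–20 seeded trials
per condition.  These sizes were chosen so that every claimed property
is checked against an independent oracle rather than asserted.

## Known limitations

- The likelihood is approximate (α = 1): totals are comparable, not
  calibrated; only rankings and differences are meaningful.
- Hill climbing with strict improvement can stall on plateaus; restarts
  mitigate but do not eliminate this, and the greedy default (strategy
  4) trades thoroughness for speed.
- The four search strategies are this package's explicit, documented
  definitions of a speed/thoroughness spectrum; other implementations
  of the same model may search differently.
- Consensus requires identical leaf sets (as produced by per-replicate
  supertree searches); no majority-rule(−) construction for partially
  overlapping leaf sets is provided.
- No weighted RF, per-tree β, NNI/TBR search neighborhoods, or
  extended-newick/NHX support.
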