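"""Score a candidate supertree against a set of input trees.

Each input tree is compared with the supertree restricted to its own
taxa; the Robinson--Foulds distance d gives a log-likelihood of -d per
tree (alpha = beta = 1), and the supertree's score is the sum.
"""

from mlsupertree import InputTreeSet, parse_newick, score_supertree

supertree = parse_newick("((human,mouse),((cat,hedgehog),(elephant,armadillo)));")
inputs = InputTreeSet([
    parse_newick("((human,mouse),(cat,hedgehog));"),       # agrees: d=0
    parse_newick("((human,cat),(mouse,hedgehog));"),       # conflicts: d=2
    parse_newick("((human,mouse),(elephant,armadillo));"), # agrees: d=0
    parse_newick("((mouse,elephant),(cat,armadillo));"),   # conflicts
])

breakdown = score_supertree(supertree, inputs)
print("per input tree (index, taxa, d, log-likelihood):")
for rec in breakdown.per_tree:
    print(f"  {rec.index}  {rec.n_overlap} taxa  d={rec.distance}  "
          f"lnL={rec.log_likelihood:+.1f}")
print(f"total log-likelihood: {breakdown.total_log_likelihood:+.1f}")
print("The total is minus the summed RF distances: each conflicting")
print("quartet costs 2 (its split and the supertree's differ).")
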