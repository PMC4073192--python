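"""Synthetic input-tree generation under the model's error process.

Input trees are simulated exactly the way the likelihood assumes they
arise: each is the true supertree restricted to a random taxon subset,
then perturbed by a random number of NNI rearrangements.  The NNI count
is Poisson with mean ``distortion_rate``, so tree probability decays
roughly exponentially with topological distance from the truth, and rate
0 gives the conflict-free regime in which the true supertree scores 0.

The defaults mirror a small phylogenomic study: a 7-taxon true tree
sampled by 100 input trees of 4--7 taxa.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .splits import robinson_foulds
from .trees import InputTreeSet, Tree, TreeError, _from_graph, prune_to_taxa
from .search import _binary_unrooted_graph

__all__ = ["SyntheticSpec", "TruthRecord", "generate_inputs", "random_binary_tree"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generator.

    ``distortion_rate`` is the expected number of NNI edits applied to
    each input tree (0 = perfect subsamples of the truth).
    """

    true_supertree: Tree
    n_trees: int = 100
    subset_size_range: Tuple[int, int] = (4, 7)
    distortion_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.subset_size_range
        n = self.true_supertree.n_leaves
        if lo < 4:
            raise ValueError("minimum subset size is 4")
        if hi > n:
            raise ValueError(f"maximum subset size {hi} exceeds {n} taxa")
        if lo > hi:
            raise ValueError("subset_size_range must be (min, max) with min <= max")
        if self.distortion_rate < 0:
            raise ValueError("distortion_rate must be non-negative")
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if not self.true_supertree.is_binary():
            raise ValueError("true supertree must be binary")


@dataclass
class TruthRecord:
    """Everything needed to audit a generated set against the truth."""

    true_supertree: Tree
    subsets: List[frozenset]
    n_edits: List[int]
    realized_distances: List[int]


def _poisson(rate: float, rng: random.Random) -> int:
    if rate <= 0:
        return 0
    # Knuth's method; rates used here are small
    limit = math.exp(-rate)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def random_nni(tree: Tree, rng: random.Random) -> Tree:
    """One random nearest-neighbor-interchange move on a binary tree."""
    adj, labels = _binary_unrooted_graph(tree)
    internal_edges = [(u, v) for u, v in
                      [(u, v) for u in adj for v in adj[u] if u < v]
                      if u not in labels and v not in labels]
    if not internal_edges:
        return tree
    u, v = internal_edges[rng.randrange(len(internal_edges))]
    a, b = sorted(n for n in adj[u] if n != v)
    c, d = sorted(n for n in adj[v] if n != u)
    swap_u = a if rng.random() < 0.5 else b
    swap_v = c if rng.random() < 0.5 else d
    adj[u].discard(swap_u)
    adj[swap_u].discard(u)
    adj[v].discard(swap_v)
    adj[swap_v].discard(v)
    adj[u].add(swap_v)
    adj[swap_v].add(u)
    adj[v].add(swap_u)
    adj[swap_u].add(v)
    return _from_graph(adj, labels)


def random_binary_tree(taxa, rng: Optional[random.Random] = None) -> Tree:
    """A uniformly grown random binary unrooted tree (random edge insertion)."""
    rng = rng if rng is not None else random.Random()
    order = sorted(frozenset(taxa))
    if len(order) < 3:
        raise TreeError("need at least 3 taxa")
    rng.shuffle(order)
    adj = {0: {1, 2, 3}, 1: {0}, 2: {0}, 3: {0}}
    labels = {1: order[0], 2: order[1], 3: order[2]}
    next_id = 4
    from .search import _attach_leaf, _undirected_edges
    for label in order[3:]:
        edges = _undirected_edges(adj)
        edge = edges[rng.randrange(len(edges))]
        next_id = _attach_leaf(adj, labels, edge, label, next_id)
    return _from_graph(adj, labels)


def generate_inputs(spec: SyntheticSpec) -> Tuple[InputTreeSet, TruthRecord]:
    """Simulate an input-tree set from a true supertree.

    For each tree: draw a uniform taxon subset of a size in range,
    restrict the truth to it, apply Poisson(distortion_rate) random NNI
    edits, and record the realized RF distance to the restricted truth.
    Deterministic for a given seed.
    """
    rng = random.Random(spec.seed)
    taxa = sorted(spec.true_supertree.taxa)
    lo, hi = spec.subset_size_range
    trees: List[Tree] = []
    subsets: List[frozenset] = []
    edits: List[int] = []
    dists: List[int] = []
    for _ in range(spec.n_trees):
        size = rng.randint(lo, hi)
        subset = frozenset(rng.sample(taxa, size))
        truth_restricted = prune_to_taxa(spec.true_supertree, subset)
        tree = truth_restricted
        k = _poisson(spec.distortion_rate, rng)
        for _ in range(k):
            tree = random_nni(tree, rng)
        trees.append(tree)
        subsets.append(subset)
        edits.append(k)
        dists.append(robinson_foulds(tree, truth_restricted))
    record = TruthRecord(spec.true_supertree, subsets, edits, dists)
    return InputTreeSet(trees), record
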