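"""Bootstrap resampling of input-tree sets and majority-rule consensus.

Support for the splits of an ML supertree is estimated by resampling the
input trees with replacement (the resampling unit is the tree, not a
character), re-running the ML search on each replicate, and summarising
the replicate optima with a majority-rule consensus; the ML tree's splits
are annotated with the percentage of replicate optima containing them.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .likelihood import SteelRodrigoModel
from .search import SearchConfig, SearchResult, run_search
from .splits import Split, splits_of
from .trees import InputTreeSet, Node, Tree, TreeError, write_newick

__all__ = [
    "SupportTree",
    "bootstrap_replicates",
    "majority_rule_consensus",
    "bootstrap_support_analysis",
    "write_support_newick",
]


@dataclass
class SupportTree:
    """A topology with per-split support percentages.

    ``support`` covers every non-trivial split of ``topology``;
    ``all_split_support`` additionally records every split observed in
    the underlying tree sample, so the support of splits absent from the
    topology can be queried too.
    """

    topology: Tree
    support: Dict[Split, float]
    all_split_support: Dict[Split, float]
    n_trees: int

    def support_for(self, split: Split) -> float:
        """Support of an arbitrary split, present in the topology or not."""
        return self.all_split_support.get(split, 0.0)


def bootstrap_replicates(inputs: InputTreeSet, n_reps: int,
                         rng: Optional[random.Random] = None) -> List[InputTreeSet]:
    """``n_reps`` resamples of the input trees, drawn with replacement.

    Each replicate has the same number of trees as the original set.
    """
    if n_reps <= 0:
        raise ValueError(f"n_reps must be positive, got {n_reps}")
    rng = rng if rng is not None else random.Random()
    n = len(inputs)
    return [InputTreeSet(inputs[rng.randrange(n)] for _ in range(n))
            for _ in range(n_reps)]


def _percentage(count: int, n: int) -> float:
    return round(100.0 * count / n, 1)


def majority_rule_consensus(trees: List[Tree],
                            threshold_percent: float = 50.0) -> SupportTree:
    """Majority-rule consensus of trees sharing one leaf set.

    The consensus contains exactly the non-trivial splits occurring in
    strictly more than ``threshold_percent`` of the trees; at thresholds
    >= 50 these are pairwise compatible by construction.  Below 50 the
    splits are inserted greedily in order of decreasing frequency,
    skipping any that conflict with those already placed.
    """
    if not trees:
        raise TreeError("consensus of an empty tree list")
    taxa = trees[0].taxa
    for i, t in enumerate(trees[1:], start=1):
        if t.taxa != taxa:
            raise TreeError(
                f"tree {i} leaf set differs from tree 0: "
                f"{sorted(t.taxa ^ taxa)}")

    counts: Dict[Split, int] = {}
    for t in trees:
        for s in splits_of(t):
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    majority = [(s, c) for s, c in counts.items()
                if 100.0 * c / n > threshold_percent]
    majority.sort(key=lambda sc: (-sc[1], len(sc[0].key), repr(sc[0])))

    ref = min(taxa)  # clades are sides not containing this reference leaf
    root = Node(children=[Node(label) for label in sorted(taxa)])
    clades: Dict[int, frozenset] = {}

    def clade(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset((node.label,))
        return frozenset().union(*(clade(c) for c in node.children))

    support: Dict[Split, float] = {}
    placed: List[Split] = []
    for split, count in majority:
        if any(not split.compatible_with(p) for p in placed):
            continue  # only reachable at thresholds < 50
        side = split.side_b if ref in split.side_a else split.side_a
        node = root
        while True:  # descend to the smallest node whose clade covers side
            nxt = next((c for c in node.children
                        if not c.is_leaf and side <= clade(c)), None)
            if nxt is None:
                break
            node = nxt
        group = [c for c in node.children if clade(c) <= side]
        if len(group) < 2 or frozenset().union(*(clade(c) for c in group)) != side:
            continue  # incompatible with the tree built so far (threshold < 50)
        node.children = [c for c in node.children if c not in group]
        node.children.append(Node(children=group))
        placed.append(split)
        support[split] = _percentage(count, n)

    topology = Tree(root, rooted=False)
    all_support = {s: _percentage(c, n) for s, c in counts.items()}
    return SupportTree(topology, support, all_support, n)


def bootstrap_support_analysis(inputs: InputTreeSet,
                               model: SteelRodrigoModel = SteelRodrigoModel(),
                               config: Optional[SearchConfig] = None,
                               n_reps: int = 20,
                               rng: Optional[random.Random] = None
                               ) -> Tuple[SupportTree, SupportTree]:
    """Full bootstrap support protocol.

    Runs the ML search on the original inputs, then on ``n_reps``
    bootstrap replicates (each replicate search derives its seed as
    ``config.seed + 1 + replicate_index``), and returns

    * the majority-rule consensus of the replicate-optimal supertrees, and
    * the original ML supertree annotated with the percentage of
      replicate optima containing each of its splits.
    """
    config = config if config is not None else SearchConfig()
    rng = rng if rng is not None else random.Random(config.seed)
    ml = run_search(inputs, model, config)

    replicates = bootstrap_replicates(inputs, n_reps, rng)
    optima: List[Tree] = []
    for i, rep in enumerate(replicates):
        rep_config = SearchConfig(strategy=config.strategy,
                                  max_iterations=config.max_iterations,
                                  n_restarts=config.n_restarts,
                                  seed=config.seed + 1 + i,
                                  start_tree=config.start_tree)
        optima.append(run_search(rep, model, rep_config).best_tree)

    consensus = majority_rule_consensus(optima)
    ml_support = {s: consensus.support_for(s) for s in splits_of(ml.best_tree)}
    annotated = SupportTree(ml.best_tree, ml_support,
                            consensus.all_split_support, n_reps)
    return consensus, annotated


def write_support_newick(sup: SupportTree) -> str:
    """Newick with split supports as internal-node labels (one decimal)."""
    tree = sup.topology.copy()
    taxa = tree.taxa
    n = len(taxa)

    def annotate(node) -> frozenset:
        if node.is_leaf:
            return frozenset((node.label,))
        below = frozenset().union(*(annotate(c) for c in node.children))
        if 2 <= len(below) <= n - 2:
            split = Split(below, taxa - below)
            if split in sup.support:
                node.label = f"{sup.support[split]:.1f}"
        return below

    for child in tree.root.children:
        annotate(child)
    return write_newick(tree)
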