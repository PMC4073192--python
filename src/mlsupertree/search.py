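"""Heuristic ML supertree search.

Hill-climbing in the space of binary unrooted supertrees under the
exponential likelihood, with SPR (subtree pruning and regrafting)
neighborhoods.  Four strategies spanning the thoroughness/speed spectrum
are provided:

1. steepest ascent — score the full SPR neighborhood each iteration and
   move to the best strictly improving neighbor;
2. first-improvement — accept the first strictly better neighbor in a
   randomly shuffled evaluation order;
3. radius-limited steepest ascent — as 1, but regraft destinations are
   confined to within 3 edges of the pruning point;
4. greedy subtree sweep — a single pass over prunable subtrees in random
   order, each immediately regrafted to its best destination when that
   strictly improves the score (the fastest, least exhaustive option, and
   the default).

All strategies accept only strict improvements (no lateral moves on the
large score plateaus typical of RF-based objectives), so trajectories are
monotone and termination is guaranteed.  Starting trees come from the
user or from randomized greedy stepwise addition.  All randomness is
drawn from a seeded generator recorded in the result.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Tuple

from .likelihood import ScoreBreakdown, SteelRodrigoModel, _overlap_total, score_supertree
from .splits import splits_of
from .trees import (InputTreeSet, Tree, TreeError, _component_leaves,
                    _from_graph, _to_graph, deroot)

__all__ = [
    "SearchConfig",
    "SearchResult",
    "stepwise_addition_start",
    "spr_neighbors",
    "run_search",
    "exhaustive_ml_supertree",
    "n_unrooted_topologies",
]


@dataclass
class SearchConfig:
    """Search settings; the defaults mirror the canonical example run
    (strategy 4, ten iterations)."""

    strategy: int = 4
    max_iterations: int = 10
    n_restarts: int = 1
    seed: int = 0
    start_tree: Optional[Tree] = None

    def __post_init__(self):
        if self.strategy not in (1, 2, 3, 4):
            raise ValueError(f"strategy must be 1..4, got {self.strategy}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be positive")


@dataclass
class SearchResult:
    best_tree: Tree
    best_score: ScoreBreakdown
    trajectory: List[Tuple[int, float]]
    n_trees_evaluated: int
    seed_used: int


# ---------------------------------------------------------------------------
# graph helpers
# ---------------------------------------------------------------------------

def _binary_unrooted_graph(tree: Tree):
    """Adjacency/labels of a tree that must be binary; deroots if needed."""
    if tree.n_leaves < 4:
        raise TreeError("need at least 4 leaves")
    base = deroot(tree)
    if not base.is_binary():
        raise TreeError("search operates on binary trees; resolve polytomies first")
    adj, labels, _ = _to_graph(base)
    return adj, labels


def _split_keys_graph(adj, labels) -> frozenset:
    """Canonical non-trivial split keys of an unrooted tree graph."""
    all_taxa = frozenset(labels.values())
    n = len(all_taxa)
    keys = set()
    for u in adj:
        for v in adj[u]:
            if u < v and v not in labels and u not in labels:
                side = _component_leaves(adj, labels, v, u)
                if 2 <= len(side) <= n - 2:
                    keys.add(frozenset((side, all_taxa - side)))
    return frozenset(keys)


def _attach_leaf(adj, labels, edge, label, next_id):
    """Subdivide ``edge`` with a new node and hang a new leaf off it."""
    x, y = edge
    w, leaf = next_id, next_id + 1
    adj[x].discard(y)
    adj[y].discard(x)
    adj[w] = {x, y, leaf}
    adj[x].add(w)
    adj[y].add(w)
    adj[leaf] = {w}
    labels[leaf] = label
    return next_id + 2


def _copy_graph(adj, labels):
    return {k: set(v) for k, v in adj.items()}, dict(labels)


def _undirected_edges(adj):
    return [(u, v) for u in adj for v in adj[u] if u < v]


# ---------------------------------------------------------------------------
# SPR neighborhood
# ---------------------------------------------------------------------------

def _spr_moves_from(adj, labels, u, v, radius=None):
    """All regrafts of the subtree on the v-side of edge (u, v).

    Yields ``(new_adj, new_labels)`` graphs.  ``u`` must be internal.
    With ``radius`` set, regraft destinations are limited to edges within
    ``radius`` edges of the pruning point (BFS from the edge created by
    suppressing u).
    """
    # nodes of the pruned component (v side)
    pruned = {v}
    stack = [v]
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb != u and nb not in pruned:
                pruned.add(nb)
                stack.append(nb)

    a, b = (n for n in adj[u] if n != v)
    remaining = {k: set(x for x in nb if x != u)
                 for k, nb in adj.items() if k not in pruned and k != u}
    remaining[a].add(b)
    remaining[b].add(a)

    targets = [e for e in _undirected_edges(remaining)
               if set(e) != {a, b}]  # regrafting on (a,b) recreates the input
    if radius is not None:
        dist = {a: 0, b: 0}
        frontier = [a, b]
        while frontier:
            nxt = []
            for node in frontier:
                for nb in remaining[node]:
                    if nb not in dist:
                        dist[nb] = dist[node] + 1
                        nxt.append(nb)
            frontier = nxt
        targets = [e for e in targets
                   if min(dist[e[0]], dist[e[1]]) < radius]

    for x, y in targets:
        new_adj = {k: set(nb) for k, nb in remaining.items()}
        for k in pruned:
            new_adj[k] = set(adj[k] - {u})
        new_adj[x].discard(y)
        new_adj[y].discard(x)
        new_adj[u] = {x, y, v}
        new_adj[x].add(u)
        new_adj[y].add(u)
        new_adj[v].add(u)
        yield new_adj


def _prune_points(adj, labels):
    """Directed edges (u, v) with internal u: each defines a prunable subtree."""
    return [(u, v) for u in adj if u not in labels for v in adj[u]]


def spr_neighbors(tree: Tree, radius: Optional[int] = None) -> Iterator[Tree]:
    """All distinct SPR rearrangements of a binary unrooted tree.

    Every edge defines a candidate subtree to prune; it is regrafted onto
    every edge of the remaining tree (optionally only those within
    ``radius`` edges of the pruning point).  Duplicate topologies and the
    original topology are filtered out.
    """
    adj, labels = _binary_unrooted_graph(tree)
    original = _split_keys_graph(adj, labels)
    seen = {original}
    for u, v in _prune_points(adj, labels):
        for new_adj in _spr_moves_from(adj, labels, u, v, radius=radius):
            keys = _split_keys_graph(new_adj, labels)
            if keys not in seen:
                seen.add(keys)
                yield _from_graph(new_adj, labels)


# ---------------------------------------------------------------------------
# starting trees
# ---------------------------------------------------------------------------

def stepwise_addition_start(taxa, inputs: InputTreeSet,
                            model: SteelRodrigoModel = SteelRodrigoModel(),
                            rng: Optional[random.Random] = None) -> Tree:
    """Randomized greedy stepwise-addition starting tree.

    The taxa are shuffled, the first three seed the unique 3-leaf tree,
    and each subsequent taxon is attached to the edge that maximises the
    supertree score against the inputs (restricted to the taxa placed so
    far); ties are broken at random.  Deterministic for a given rng state.
    """
    rng = rng if rng is not None else random.Random()
    order = sorted(frozenset(taxa))
    if len(order) < 3:
        raise TreeError("stepwise addition needs at least 3 taxa")
    rng.shuffle(order)
    profiles = inputs.split_profiles()

    adj = {0: {1, 2, 3}, 1: {0}, 2: {0}, 3: {0}}
    labels = {1: order[0], 2: order[1], 3: order[2]}
    next_id = 4
    for label in order[3:]:
        best: list = []
        best_score = None
        for edge in _undirected_edges(adj):
            cand_adj, cand_labels = _copy_graph(adj, labels)
            _attach_leaf(cand_adj, cand_labels, edge, label, next_id)
            tree = _from_graph(cand_adj, cand_labels)
            pairs = tuple((s.side_a, s.side_b) for s in splits_of(tree))
            score = _overlap_total(pairs, tree.taxa, profiles, model)
            if best_score is None or score > best_score + 1e-12:
                best, best_score = [edge], score
            elif abs(score - best_score) <= 1e-12:
                best.append(edge)
        edge = rng.choice(best)
        next_id = _attach_leaf(adj, labels, edge, label, next_id)
    return _from_graph(adj, labels)


# ---------------------------------------------------------------------------
# hill climbing
# ---------------------------------------------------------------------------

class _Scorer:
    """Scoring closure with an evaluation counter."""

    def __init__(self, inputs: InputTreeSet, model: SteelRodrigoModel):
        self.inputs = inputs
        self.model = model
        self.n_evaluated = 0

    def total(self, tree: Tree) -> float:
        self.n_evaluated += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return score_supertree(tree, self.inputs, self.model).total_log_likelihood


def _climb(start: Tree, scorer: _Scorer, config: SearchConfig,
           rng: random.Random):
    """One hill-climbing run; returns (tree, total, trajectory)."""
    current = start
    current_total = scorer.total(current)
    trajectory = [(0, current_total)]
    radius = 3 if config.strategy == 3 else None

    for iteration in range(1, config.max_iterations + 1):
        improved = False
        if config.strategy in (1, 3):
            best_nbrs, best_total = [], current_total
            for nbr in spr_neighbors(current, radius=radius):
                t = scorer.total(nbr)
                if t > best_total + 1e-12:
                    best_nbrs, best_total = [nbr], t
                elif best_nbrs and abs(t - best_total) <= 1e-12:
                    best_nbrs.append(nbr)
            if best_nbrs:
                current, current_total = rng.choice(best_nbrs), best_total
                improved = True
        elif config.strategy == 2:
            nbrs = list(spr_neighbors(current))
            rng.shuffle(nbrs)
            for nbr in nbrs:
                t = scorer.total(nbr)
                if t > current_total + 1e-12:
                    current, current_total = nbr, t
                    improved = True
                    break
        else:  # strategy 4: greedy subtree sweep
            adj, labels = _binary_unrooted_graph(current)
            sides = [_component_leaves(adj, labels, v, u)
                     for u, v in _prune_points(adj, labels)]
            rng.shuffle(sides)
            for side in sides:
                adj, labels = _binary_unrooted_graph(current)
                point = next(((u, v) for u, v in _prune_points(adj, labels)
                              if _component_leaves(adj, labels, v, u) == side),
                             None)
                if point is None:  # subtree no longer present after earlier moves
                    continue
                best_tree, best_total = None, current_total
                seen = {_split_keys_graph(adj, labels)}
                for new_adj in _spr_moves_from(adj, labels, *point):
                    keys = _split_keys_graph(new_adj, labels)
                    if keys in seen:
                        continue
                    seen.add(keys)
                    nbr = _from_graph(new_adj, labels)
                    t = scorer.total(nbr)
                    if t > best_total + 1e-12:
                        best_tree, best_total = nbr, t
                if best_tree is not None:
                    current, current_total = best_tree, best_total
                    improved = True
        trajectory.append((iteration, current_total))
        if not improved:
            break
    return current, current_total, trajectory


def run_search(inputs: InputTreeSet,
               model: SteelRodrigoModel = SteelRodrigoModel(),
               config: Optional[SearchConfig] = None) -> SearchResult:
    """Heuristic search for the supertree of highest likelihood.

    Starts from ``config.start_tree`` (polytomies resolved at random with
    a warning) or from a stepwise-addition tree, then hill-climbs with
    the configured SPR strategy.  With ``n_restarts > 1`` the whole
    procedure repeats from fresh random starts and the overall best is
    returned.  Fully reproducible for a given seed.
    """
    config = config if config is not None else SearchConfig()
    rng = random.Random(config.seed)
    union = inputs.union_taxa
    if len(union) < 4:
        raise TreeError("supertree search needs at least 4 taxa overall")

    start_given = None
    if config.start_tree is not None:
        missing = union - config.start_tree.taxa
        if missing:
            raise TreeError(f"start tree is missing taxa: {sorted(missing)}")
        start_given = config.start_tree
        if not deroot(start_given).is_binary():
            from .toolbox import resolve_polytomies_random
            warnings.warn("start tree has polytomies; resolving at random")
            start_given = resolve_polytomies_random(start_given, rng)

    scorer = _Scorer(inputs, model)
    best_tree = best_total = best_traj = None
    for restart in range(config.n_restarts):
        if restart == 0 and start_given is not None:
            start = start_given
        else:
            start = stepwise_addition_start(union, inputs, model, rng)
        tree, total, traj = _climb(start, scorer, config, rng)
        if best_total is None or total > best_total:
            best_tree, best_total, best_traj = tree, total, traj

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        breakdown = score_supertree(best_tree, inputs, model)
    return SearchResult(best_tree, breakdown, best_traj,
                        scorer.n_evaluated, config.seed)


# ---------------------------------------------------------------------------
# exhaustive enumeration (small-instance oracle)
# ---------------------------------------------------------------------------

def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! — the number of binary unrooted topologies on n >= 3 leaves."""
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


def enumerate_topologies(taxa) -> Iterator[Tree]:
    """All binary unrooted topologies on a taxon set, in a fixed order.

    Generated by recursive edge insertion over the taxa in sorted order,
    so the sequence is deterministic.
    """
    order = sorted(frozenset(taxa))
    if len(order) < 3:
        raise TreeError("need at least 3 taxa")

    def recurse(adj, labels, next_id, remaining):
        if not remaining:
            yield _from_graph(adj, labels)
            return
        label, rest = remaining[0], remaining[1:]
        for edge in _undirected_edges(adj):
            cand_adj, cand_labels = _copy_graph(adj, labels)
            nid = _attach_leaf(cand_adj, cand_labels, edge, label, next_id)
            yield from recurse(cand_adj, cand_labels, nid, rest)

    adj = {0: {1, 2, 3}, 1: {0}, 2: {0}, 3: {0}}
    labels = {1: order[0], 2: order[1], 3: order[2]}
    yield from recurse(adj, labels, 4, order[3:])


def exhaustive_ml_supertree(inputs: InputTreeSet,
                            model: SteelRodrigoModel = SteelRodrigoModel(),
                            return_all: bool = False):
    """Globally optimal supertree by brute-force enumeration.

    Scores every binary unrooted topology on the union taxon set
    ((2n-5)!! of them; limited to n <= 8).  Returns ``(tree, breakdown)``
    for the first optimum in enumeration order, or with
    ``return_all=True`` a list of all co-optimal trees alongside it.
    """
    union = inputs.union_taxa
    if len(union) > 8:
        raise TreeError(
            f"{len(union)} taxa give {n_unrooted_topologies(len(union))} "
            "topologies; use run_search instead")
    best_tree = best = None
    co_optima: list = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tree in enumerate_topologies(union):
            bd = score_supertree(tree, inputs, model)
            if best is None or bd.total_log_likelihood > best.total_log_likelihood + 1e-12:
                best_tree, best = tree, bd
                co_optima = [tree]
            elif abs(bd.total_log_likelihood - best.total_log_likelihood) <= 1e-12:
                co_optima.append(tree)
    if return_all:
        return best_tree, best, co_optima
    return best_tree, best
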