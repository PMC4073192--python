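"""Canonical split (bipartition) encoding and the Robinson--Foulds distance.

A split is the bipartition of the leaf set induced by removing one tree
edge.  The Robinson--Foulds distance d between two trees on the same leaf
set is the size of the symmetric difference of their non-trivial split
sets — the full, unhalved count, so a pair of fully resolved but entirely
conflicting n-leaf trees is at distance 2(n-3).  This d is the quantity
the exponential supertree likelihood is built on.
"""

from __future__ import annotations

from typing import FrozenSet, Iterable, Optional

from .trees import Tree, TreeError

__all__ = ["Split", "splits_of", "robinson_foulds", "restrict_split_keys"]


class Split:
    """An unordered bipartition {side_a, side_b} of a reference taxon set.

    Equality and hashing are orientation-free: ``Split(A, B) == Split(B, A)``.
    """

    __slots__ = ("side_a", "side_b", "key")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        side_a = frozenset(side_a)
        side_b = frozenset(side_b)
        if not side_a or not side_b:
            raise TreeError("both sides of a split must be non-empty")
        if side_a & side_b:
            raise TreeError("split sides must be disjoint")
        self.side_a = side_a
        self.side_b = side_b
        self.key = frozenset((side_a, side_b))

    @property
    def taxa(self) -> FrozenSet[str]:
        return self.side_a | self.side_b

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) < 2

    def restrict(self, taxa: Iterable[str]) -> Optional["Split"]:
        """The split induced on a taxon subset, or None if it degenerates."""
        taxa = frozenset(taxa)
        a = self.side_a & taxa
        b = self.side_b & taxa
        if not a or not b:
            return None
        return Split(a, b)

    def compatible_with(self, other: "Split") -> bool:
        """Compatibility on shared taxa: some cross-intersection is empty."""
        shared = self.taxa & other.taxa
        a, b = self.side_a & shared, self.side_b & shared
        c, d = other.side_a & shared, other.side_b & shared
        return not (a & c and a & d and b & c and b & d)

    def __eq__(self, other) -> bool:
        return isinstance(other, Split) and self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __repr__(self) -> str:
        fmt = lambda s: " ".join(sorted(s))
        a, b = sorted((self.side_a, self.side_b), key=lambda s: sorted(s)[0])
        return f"{fmt(a)} | {fmt(b)}"


def splits_of(tree: Tree) -> FrozenSet[Split]:
    """The non-trivial splits of (the unrooted view of) a tree.

    A binary unrooted tree on n >= 4 leaves has exactly n-3; trees on
    fewer than 4 leaves have none.  Rooting is immaterial: the two edges
    of a bifurcating root induce the same bipartition and are collapsed
    by the set encoding.
    """
    taxa = tree.taxa
    n = len(taxa)
    if n < 4:
        return frozenset()

    out = set()

    def walk(node) -> frozenset:
        if node.is_leaf:
            return frozenset((node.label,))
        below = frozenset().union(*(walk(c) for c in node.children))
        if 2 <= len(below) <= n - 2:
            out.add(Split(below, taxa - below))
        return below

    for child in tree.root.children:
        walk(child)
    return frozenset(out)


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Symmetric-difference (RF) distance between trees on one leaf set.

    Both directions of the symmetric difference are counted.  The caller
    is responsible for pruning to a common taxon set first; unequal leaf
    sets are an error.
    """
    if t1.taxa != t2.taxa:
        only1 = sorted(t1.taxa - t2.taxa)
        only2 = sorted(t2.taxa - t1.taxa)
        raise TreeError(
            "leaf sets differ: "
            f"only in first = {only1}, only in second = {only2}")
    k1 = {s.key for s in splits_of(t1)}
    k2 = {s.key for s in splits_of(t2)}
    return len(k1 ^ k2)


def restrict_split_keys(side_pairs, taxa: frozenset) -> set:
    """Canonical keys of split restrictions to a taxon subset.

    ``side_pairs`` is an iterable of ``(side_a, side_b)`` frozenset pairs.
    Restrictions that degenerate (a side with < 2 taxa) are dropped;
    coincident restrictions collapse, exactly as pruning the tree would
    merge them.
    """
    out = set()
    for sa, sb in side_pairs:
        ra = sa & taxa
        if len(ra) < 2:
            continue
        rb = sb & taxa
        if len(rb) < 2:
            continue
        out.add(frozenset((ra, rb)))
    return out
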