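"""Utility operations on trees and tree files.

Polytomy resolution (random or guided by a reference tree), batch
pruning, newick/NEXUS conversion and taxon-set extraction.  All utilities
preserve file order and are deterministic under a seeded rng.
"""

from __future__ import annotations

import random
import warnings
from typing import Iterable, List, Optional, Tuple

from .splits import Split, splits_of
from .trees import (InputTreeSet, Node, Tree, TreeError, parse_newick,
                    parse_tree_file, prune_to_taxa, write_newick)

__all__ = [
    "resolve_polytomies_random",
    "resolve_polytomies_with_reference",
    "prune_trees",
    "prune_file",
    "convert_format",
    "extract_taxa",
]


def resolve_polytomies_random(tree: Tree,
                              rng: Optional[random.Random] = None) -> Tree:
    """Resolve every polytomy by repeatedly joining two random children.

    Every original split is preserved; the new splits only refine the
    polytomies.  An unrooted tree keeps a trifurcating base; already
    binary trees come back unchanged (up to copying).
    """
    rng = rng if rng is not None else random.Random()
    out = tree.copy()

    def resolve(node: Node, target: int) -> None:
        for child in node.children:
            if not child.is_leaf:
                resolve(child, 2)
        while len(node.children) > target:
            i, j = sorted(rng.sample(range(len(node.children)), 2))
            joined = Node(children=[node.children[i], node.children[j]])
            node.children = [c for k, c in enumerate(node.children)
                             if k not in (i, j)]
            node.children.append(joined)

    root_target = 2 if (tree.rooted or tree.n_leaves < 3) else 3
    resolve(out.root, root_target)
    return Tree(out.root, out.rooted)


def resolve_polytomies_with_reference(tree: Tree, reference: Tree,
                                      rng: Optional[random.Random] = None) -> Tree:
    """Resolve polytomies to agree with a reference tree where it is
    informative; residual ambiguity is resolved at random.

    Each polytomy is reduced by joining two of its children at a time,
    always preferring a pair whose induced split matches a reference
    split (restricted to the shared taxa) and never choosing a pair whose
    induced split conflicts with the reference when a non-conflicting
    pair exists.  All original splits are preserved.
    """
    rng = rng if rng is not None else random.Random()
    missing = tree.taxa - reference.taxa
    if missing:
        raise TreeError(f"reference is missing taxa: {sorted(missing)}")
    ref_splits = [s.restrict(tree.taxa) for s in splits_of(reference)]
    ref_splits = [s for s in ref_splits if s is not None and not s.is_trivial]
    taxa = tree.taxa
    out = tree.copy()

    def clade(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset((node.label,))
        return frozenset().union(*(clade(c) for c in node.children))

    def pair_rank(children: List[Node], i: int, j: int):
        merged = clade(children[i]) | clade(children[j])
        if len(taxa - merged) < 2 or len(merged) < 2:
            return (1, 0)  # trivial within the full tree: never conflicts
        cand = Split(merged, taxa - merged)
        if any(not cand.compatible_with(r) for r in ref_splits):
            return (2, 0)  # conflicting: last resort only
        matches = any(cand == r for r in ref_splits)
        return (0, 0) if matches else (1, 0)

    def resolve(node: Node, target: int) -> None:
        for child in node.children:
            if not child.is_leaf:
                resolve(child, 2)
        while len(node.children) > target:
            pairs = [(i, j) for i in range(len(node.children))
                     for j in range(i + 1, len(node.children))]
            ranked = [(pair_rank(node.children, i, j), (i, j)) for i, j in pairs]
            best = min(r for r, _ in ranked)
            choices = [p for r, p in ranked if r == best]
            i, j = choices[rng.randrange(len(choices))]
            joined = Node(children=[node.children[i], node.children[j]])
            node.children = [c for k, c in enumerate(node.children)
                             if k not in (i, j)]
            node.children.append(joined)

    root_target = 2 if (tree.rooted or tree.n_leaves < 3) else 3
    resolve(out.root, root_target)
    return Tree(out.root, out.rooted)


def prune_trees(trees: Iterable[Tree], keep: Iterable[str]) -> List[Tree]:
    """Prune each tree to ``keep``; drop trees sharing < 2 taxa with it.

    Dropped trees are reported with a warning; an empty result is an
    error.
    """
    keep = frozenset(keep)
    out: List[Tree] = []
    dropped: List[int] = []
    for i, tree in enumerate(trees):
        if len(tree.taxa & keep) < 2:
            dropped.append(i)
            continue
        out.append(prune_to_taxa(tree, keep))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} tree(s) sharing fewer than 2 taxa "
            f"with the keep set (indices {dropped})")
    if not out:
        raise TreeError("pruning removed every tree")
    return out


def prune_file(in_path, keep: Iterable[str], out_path,
               format: str = "newick") -> int:
    """File-level pruning; returns the number of trees written."""
    inputs = parse_tree_file(in_path, format=format)
    pruned = prune_trees(inputs, keep)
    with open(out_path, "w") as fh:
        for t in pruned:
            fh.write(write_newick(t) + "\n")
    return len(pruned)


def convert_format(in_path, out_path, direction: str) -> int:
    """Convert between newick and NEXUS tree files, losslessly for
    topology and labels.  ``direction`` is ``nexus->newick`` or
    ``newick->nexus``; TRANSLATE tables are expanded on read and
    regenerated on write.  Returns the number of trees converted.
    """
    import dendropy
    if direction == "nexus->newick":
        inputs = parse_tree_file(in_path, format="nexus")
        with open(out_path, "w") as fh:
            for t in inputs:
                fh.write(write_newick(t) + "\n")
        return len(inputs)
    if direction == "newick->nexus":
        inputs = parse_tree_file(in_path, format="newick")
        tl = dendropy.TreeList()
        for t in inputs:
            tl.append(dendropy.Tree.get(data=write_newick(t), schema="newick",
                                        taxon_namespace=tl.taxon_namespace,
                                        preserve_underscores=True))
        tl.write(path=str(out_path), schema="nexus", translate_tree_taxa=True,
                 suppress_rooting=True, unquoted_underscores=True)
        return len(inputs)
    raise ValueError(f"unknown direction {direction!r}")


def extract_taxa(trees: Iterable[Tree]) -> Tuple[List[frozenset], frozenset]:
    """Per-tree leaf sets (in order) and their union."""
    per_tree = [t.taxa for t in trees]
    union: frozenset = frozenset()
    for s in per_tree:
        union = union | s
    return per_tree, union
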