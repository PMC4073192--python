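"""Tree data model, newick/NEXUS I/O and elementary topology surgery.

Trees are stored as parsed (rooted if the root is bifurcating, unrooted
otherwise).  Branch lengths and internal-node labels are carried through
I/O but never affect any topological comparison: the Robinson--Foulds
distance used throughout the package is purely a function of split sets.
Tree objects are treated as immutable once built; every operation returns
a new tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "Tree",
    "TreeError",
    "NewickParseError",
    "TaxonSet",
    "InputTreeSet",
    "Node",
    "parse_newick",
    "write_newick",
    "parse_tree_file",
    "write_tree_file",
    "prune_to_taxa",
    "deroot",
    "reroot",
]

# A taxon set is a plain frozenset of leaf-label strings (order-free, no
# duplicates by construction).
TaxonSet = frozenset


class TreeError(ValueError):
    """Invalid tree or invalid operation on a tree."""


class NewickParseError(TreeError):
    """Malformed newick input; ``offset`` is the 0-based character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class Node:
    """One vertex of a tree: a leaf (label set) or an internal node."""

    __slots__ = ("label", "children", "length")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[list] = None,
                 length: Optional[float] = None):
        self.label = label
        self.children: list[Node] = children if children is not None else []
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(self.label, [c.copy() for c in self.children], self.length)


class Tree:
    """A leaf-labelled topology, rooted or unrooted.

    ``rooted`` follows the usual convention: a bifurcating root marks a
    rooted tree, a root of degree >= 3 an unrooted one.  Leaf labels are
    unique; internal nodes have >= 2 children (except the trivial
    single-leaf tree).
    """

    __slots__ = ("root", "rooted", "_leaf_cache")

    def __init__(self, root: Node, rooted: Optional[bool] = None):
        self.root = root
        if rooted is None:
            rooted = len(root.children) == 2 or root.is_leaf
        self.rooted = rooted
        self._leaf_cache: Optional[frozenset] = None
        self._validate()

    # -- structure -----------------------------------------------------
    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.postorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("leaf with empty label")
                if node.label in seen:
                    raise TreeError(f"duplicate leaf label {node.label!r}")
                seen.add(node.label)
            elif len(node.children) < 2:
                raise TreeError("internal node of degree 2 (unary child)")

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                stack.extend((c, False) for c in reversed(node.children))

    @property
    def taxa(self) -> frozenset:
        if self._leaf_cache is None:
            self._leaf_cache = frozenset(
                n.label for n in self.postorder() if n.is_leaf)
        return self._leaf_cache

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    def is_binary(self) -> bool:
        """True if fully resolved (allowing the conventional root degrees)."""
        for node in self.postorder():
            if node.is_leaf or node is self.root:
                continue
            if len(node.children) != 2:
                return False
        permitted = (2,) if self.rooted else (2, 3)
        return self.root.is_leaf or len(self.root.children) in permitted

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), self.rooted)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({write_newick(self)!r})"


# ---------------------------------------------------------------------------
# newick parsing / writing
# ---------------------------------------------------------------------------

_RESERVED = set("(),:;")


class _NewickScanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        self.skip_ws()
        if self.pos >= len(self.text):
            raise NewickParseError("unexpected end of input", self.pos)
        return self.text[self.pos]

    def expect(self, ch: str) -> None:
        got = self.peek()
        if got != ch:
            raise NewickParseError(f"expected {ch!r}, found {got!r}", self.pos)
        self.pos += 1

    def label(self, required: bool = False) -> Optional[str]:
        self.skip_ws()
        if self.pos < len(self.text) and self.text[self.pos] == "'":
            return self._quoted_label()
        start = self.pos
        while (self.pos < len(self.text)
               and self.text[self.pos] not in _RESERVED
               and not self.text[self.pos].isspace()):
            self.pos += 1
        raw = self.text[start:self.pos]
        if not raw:
            if required:
                raise NewickParseError("empty label", start)
            return None
        return raw

    def _quoted_label(self) -> str:
        start = self.pos
        self.pos += 1  # opening quote
        chunks: list[str] = []
        while True:
            if self.pos >= len(self.text):
                raise NewickParseError("unterminated quoted label", start)
            ch = self.text[self.pos]
            if ch == "'":
                if self.pos + 1 < len(self.text) and self.text[self.pos + 1] == "'":
                    chunks.append("'")
                    self.pos += 2
                else:
                    self.pos += 1
                    break
            else:
                chunks.append(ch)
                self.pos += 1
        if not chunks:
            raise NewickParseError("empty quoted label", start)
        return "".join(chunks)

    def number(self) -> float:
        self.skip_ws()
        start = self.pos
        while (self.pos < len(self.text)
               and (self.text[self.pos] in "+-.eE0123456789")):
            # stop if 'e'/'E' begins a label rather than an exponent
            self.pos += 1
        raw = self.text[start:self.pos]
        try:
            return float(raw)
        except ValueError:
            raise NewickParseError(f"invalid branch length {raw!r}", start) from None


def parse_newick(text: str) -> Tree:
    """Parse a single ``;``-terminated newick statement into a Tree.

    Unquoted labels are runs of characters excluding ``( ) , : ;`` and
    whitespace; single-quoted labels are accepted and unescaped.
    Polytomies are preserved; branch lengths are stored when present.
    Raises :class:`NewickParseError` naming the character offset on
    malformed input.
    """
    sc = _NewickScanner(text)

    def subtree() -> Node:
        if sc.peek() == "(":
            open_pos = sc.pos
            sc.expect("(")
            children = [subtree()]
            while sc.peek() == ",":
                sc.expect(",")
                children.append(subtree())
            if sc.peek() != ")":
                raise NewickParseError("unbalanced parentheses", open_pos)
            sc.expect(")")
            node = Node(children=children)
            node.label = sc.label()
        else:
            node = Node(label=sc.label(required=True))
        sc.skip_ws()
        if sc.pos < len(sc.text) and sc.text[sc.pos] == ":":
            sc.pos += 1
            node.length = sc.number()
        return node

    root = subtree()
    if sc.peek() != ";":
        raise NewickParseError("missing ';' terminator", sc.pos)
    sc.pos += 1
    sc.skip_ws()
    if sc.pos != len(sc.text):
        raise NewickParseError("trailing characters after ';'", sc.pos)
    try:
        return Tree(root)
    except TreeError as exc:
        raise NewickParseError(str(exc), 0) from None


def _format_length(x: float) -> str:
    # repr() gives the shortest digit string that round-trips the float
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


def _needs_quoting(label: str) -> bool:
    return any(ch in _RESERVED or ch.isspace() or ch == "'" for ch in label)


def _format_label(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree) -> str:
    """Serialise a tree to a ``;``-terminated newick string."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            out = _format_label(node.label)
        else:
            out = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                out += _format_label(node.label)
        if node.length is not None:
            out += ":" + _format_length(node.length)
        return out

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# tree collections
# ---------------------------------------------------------------------------

@dataclass
class InputTreeSet:
    """An ordered collection of (partially overlapping) input trees.

    Order is significant: CONSEL matrix rows and winning-sites tallies are
    index-aligned with this ordering.  Split profiles are computed lazily
    and cached, which makes repeated supertree scoring cheap.
    """

    trees: tuple
    _profiles: Optional[list] = field(default=None, repr=False, compare=False)

    def __init__(self, trees: Iterable[Tree]):
        self.trees = tuple(trees)
        if not self.trees:
            raise TreeError("empty input tree set")
        self._profiles = None

    @property
    def union_taxa(self) -> frozenset:
        out: frozenset = frozenset()
        for t in self.trees:
            out = out | t.taxa
        return out

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[Tree]:
        return iter(self.trees)

    def __getitem__(self, i: int) -> Tree:
        return self.trees[i]

    def split_profiles(self) -> list:
        """Per-tree ``(taxa, split_side_pairs, split_keys)``, cached."""
        if self._profiles is None:
            from .splits import splits_of  # local import avoids a cycle
            profiles = []
            for t in self.trees:
                sp = splits_of(t)
                pairs = tuple((s.side_a, s.side_b) for s in sp)
                keys = frozenset(s.key for s in sp)
                profiles.append((t.taxa, pairs, keys))
            self._profiles = profiles
        return self._profiles


def parse_tree_file(path, format: str = "newick") -> InputTreeSet:
    """Read a tree file into an :class:`InputTreeSet`, preserving order.

    ``newick``: one ``;``-terminated tree per line, blank lines ignored;
    parse errors are reported with the offending line number.
    ``nexus``: a TREES block, with TRANSLATE tables resolved.
    """
    if format == "newick":
        trees = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    trees.append(parse_newick(line))
                except NewickParseError as exc:
                    raise TreeError(f"{path}, line {lineno}: {exc}") from None
        if not trees:
            raise TreeError(f"{path}: no trees found")
        return InputTreeSet(trees)
    if format == "nexus":
        import dendropy
        try:
            tl = dendropy.TreeList.get(path=str(path), schema="nexus",
                                       preserve_underscores=True)
        except Exception as exc:
            raise TreeError(f"{path}: NEXUS parse failure: {exc}") from None
        if not tl:
            raise TreeError(f"{path}: no trees found in TREES block")
        trees = [
            parse_newick(t.as_string(schema="newick", suppress_rooting=True,
                                     unquoted_underscores=True).strip())
            for t in tl
        ]
        return InputTreeSet(trees)
    raise ValueError(f"unknown format {format!r}")


def write_tree_file(trees: Iterable[Tree], path) -> None:
    """Write trees as newick, one per line, in order."""
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------------
# topology surgery
# ---------------------------------------------------------------------------

def _combine_lengths(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def prune_to_taxa(tree: Tree, keep: Iterable[str]) -> Tree:
    """Restrict a tree to ``keep ∩ leaves``, suppressing unary nodes.

    The relative topology of the retained leaves is preserved: every split
    of the result is the restriction of a split of the input.  Edge lengths
    along suppressed paths are summed.
    """
    keep = frozenset(keep)
    inter = keep & tree.taxa
    if not inter:
        raise TreeError("pruning would remove every leaf (empty intersection)")

    def prune(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.label in inter:
                return Node(node.label, length=node.length)
            return None
        kids = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            child.length = _combine_lengths(node.length, child.length)
            return child
        return Node(node.label, kids, node.length)

    root = prune(tree.root)
    assert root is not None
    root.length = None  # a root edge is meaningless after suppression
    return Tree(root)


def deroot(tree: Tree) -> Tree:
    """Remove a bifurcating root by merging its two child edges.

    Idempotent on already-unrooted trees; the unrooted split set is
    unchanged.  Requires >= 3 leaves.
    """
    if tree.n_leaves < 3:
        raise TreeError("cannot deroot a tree with fewer than 3 leaves")
    if len(tree.root.children) != 2:
        out = tree.copy()
        out.rooted = False
        return out
    root = tree.root.copy()
    a, b = root.children
    # merge into whichever child is internal; one must be, with >=3 leaves
    host, other = (a, b) if not a.is_leaf else (b, a)
    other.length = _combine_lengths(a.length, b.length)
    host.children.append(other)
    host.length = None
    host.label = None
    return Tree(host, rooted=False)


def reroot(tree: Tree, outgroup: Iterable[str]) -> Tree:
    """Root a tree on the edge separating ``outgroup`` from the rest.

    The outgroup must be a proper subset of the leaves and must form a
    split of the unrooted tree (any single leaf always qualifies).  The
    unrooted split set is unchanged.
    """
    outgroup = frozenset(outgroup)
    taxa = tree.taxa
    if not outgroup or not outgroup < taxa:
        raise TreeError("outgroup must be a non-empty proper subset of the leaves")
    if tree.n_leaves == 2:  # only one rooted shape exists
        out = tree.copy()
        out.rooted = True
        return out
    base = deroot(tree)
    adj, labels, lengths = _to_graph(base)
    n_total = len(taxa)

    # leafsets of the v-side of each directed edge (u, v)
    target = None
    for u in adj:
        for v in adj[u]:
            side = _component_leaves(adj, labels, v, u)
            if side == outgroup:
                target = (u, v)
                break
        if target:
            break
    if target is None:
        raise TreeError("outgroup not monophyletic: not a split of the tree")

    u, v = target
    new_id = max(adj) + 1
    length = lengths.get(frozenset((u, v)))
    half = None if length is None else length / 2.0
    adj[u].discard(v)
    adj[v].discard(u)
    adj[new_id] = {u, v}
    adj[u].add(new_id)
    adj[v].add(new_id)
    lengths[frozenset((new_id, u))] = half
    lengths[frozenset((new_id, v))] = half
    return _from_graph(adj, labels, lengths, root=new_id, rooted=True)


# ---------------------------------------------------------------------------
# undirected-graph view (shared with the SPR search machinery)
# ---------------------------------------------------------------------------

def _to_graph(tree: Tree):
    """Return (adjacency, leaf-labels, edge-lengths) with integer node ids."""
    adj: dict = {}
    labels: dict = {}
    lengths: dict = {}
    counter = itertools.count()

    def walk(node: Node) -> int:
        nid = next(counter)
        adj[nid] = set()
        if node.is_leaf:
            labels[nid] = node.label
        for child in node.children:
            cid = walk(child)
            adj[nid].add(cid)
            adj[cid].add(nid)
            lengths[frozenset((nid, cid))] = child.length
        return nid

    walk(tree.root)
    return adj, labels, lengths


def _component_leaves(adj, labels, start, blocked) -> frozenset:
    """Leaf labels reachable from ``start`` without crossing ``blocked``."""
    seen = {blocked, start}
    stack = [start]
    out = []
    while stack:
        node = stack.pop()
        if node in labels:
            out.append(labels[node])
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return frozenset(out)


def _from_graph(adj, labels, lengths=None, root=None, rooted=False) -> Tree:
    """Orient an undirected tree graph into a Tree rooted at ``root``.

    With no root given, an internal node is chosen (yielding the usual
    unrooted representation with a multifurcating base).
    """
    if root is None:
        internals = [n for n in adj if n not in labels]
        root = internals[0] if internals else next(iter(adj))

    def build(nid, parent) -> Node:
        node = Node(label=labels.get(nid))
        for nb in sorted(adj[nid]):
            if nb != parent:
                child = build(nb, nid)
                if lengths is not None:
                    child.length = lengths.get(frozenset((nid, nb)))
                node.children.append(child)
        return node

    return Tree(build(root, None), rooted=rooted)
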