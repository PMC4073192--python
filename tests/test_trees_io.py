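"""Tree model, newick/NEXUS I/O and topology surgery."""

import random
import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlsupertree import (InputTreeSet, NewickParseError, Tree, TreeError,
                         deroot, parse_newick, parse_tree_file, prune_to_taxa,
                         reroot, splits_of, write_newick, write_tree_file)
from conftest import random_polytomous_tree


class TestParseNewick:
    def test_smallest_informative_tree(self, quartet_ab_cd):
        assert quartet_ab_cd.taxa == frozenset("ABCD")
        assert quartet_ab_cd.rooted
        assert len(splits_of(quartet_ab_cd)) == 1

    def test_polytomy_and_branch_length(self):
        t = parse_newick("(A,B,(C,D):0.5);")
        assert len(t.root.children) == 3
        assert not t.rooted
        cd = t.root.children[2]
        assert cd.length == 0.5

    @pytest.mark.parametrize("bad", [
        "((A,B),(C,D)",        # unbalanced parentheses
        "((A,B),(C,D))",       # missing semicolon
        "(A,,B);",             # empty label
        "(A,B,A);",            # duplicate label
        "(A,B));",             # trailing garbage
        "",                    # empty input
    ])
    def test_malformed_input_raises_with_offset(self, bad):
        with pytest.raises(NewickParseError) as exc:
            parse_newick(bad)
        assert "character" in str(exc.value)

    def test_quoted_labels_unescaped(self):
        t = parse_newick("('sea cow','o''possum');")
        assert t.taxa == frozenset({"sea cow", "o'possum"})
        # and they survive writing
        assert parse_newick(write_newick(t)).taxa == t.taxa

    def test_internal_labels_carried(self):
        t = parse_newick("((A,B)clade1,(C,D));")
        assert t.root.children[0].label == "clade1"


class TestWriteNewick:
    def test_single_leaf_degenerate(self):
        assert write_newick(parse_newick("A;")) == "A;"

    def test_lengths_round_trip_full_precision(self):
        t = parse_newick("((A:0.123456789012345,B:1e-09),C:3.0);")
        t2 = parse_newick(write_newick(t))
        lengths = sorted(n.length for n in t2.postorder() if n.length is not None)
        assert lengths == [1e-09, 0.123456789012345, 3.0]

    def test_round_trip_split_set(self, quartet_ab_cd):
        assert splits_of(parse_newick(write_newick(quartet_ab_cd))) == \
            splits_of(quartet_ab_cd)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(0, 10**6), st.integers(4, 30))
def test_write_parse_round_trip_preserves_splits(seed, n_taxa):
    """Split set is invariant under write -> parse, polytomies included."""
    rng = random.Random(seed)
    taxa = [f"t{i}" for i in range(n_taxa)]
    tree = random_polytomous_tree(taxa, rng)
    again = parse_newick(write_newick(tree))
    assert again.taxa == tree.taxa
    assert splits_of(again) == splits_of(tree)


class TestPrune:
    def test_prune_matches_split_restriction(self):
        t = parse_newick("((A,B),(C,(D,E)));")
        pruned = prune_to_taxa(t, {"A", "B", "C", "D"})
        assert pruned.taxa == frozenset("ABCD")
        assert splits_of(pruned) == splits_of(parse_newick("((A,B),(C,D));"))

    def test_prune_to_full_leaf_set_is_identity(self, quartet_ab_cd):
        assert splits_of(prune_to_taxa(quartet_ab_cd, quartet_ab_cd.taxa)) == \
            splits_of(quartet_ab_cd)

    def test_prune_to_two_leaves(self, quartet_ab_cd):
        p = prune_to_taxa(quartet_ab_cd, {"A", "C"})
        assert p.taxa == frozenset("AC")

    def test_empty_intersection_errors(self, quartet_ab_cd):
        with pytest.raises(TreeError):
            prune_to_taxa(quartet_ab_cd, {"X", "Y"})


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(0, 10**6))
def test_pruning_soundness_against_split_restriction(seed):
    """Every split of the pruned tree is the restriction of an original
    split with both sides non-empty (brute-force restriction oracle)."""
    rng = random.Random(seed)
    n = rng.randint(5, 15)
    taxa = [f"t{i}" for i in range(n)]
    tree = random_polytomous_tree(taxa, rng)
    k = rng.randint(2, n - 1)
    keep = frozenset(rng.sample(taxa, k))
    pruned = prune_to_taxa(tree, keep)
    assert pruned.taxa == keep & tree.taxa
    restrictions = {s.restrict(keep) for s in splits_of(tree)}
    restrictions = {s.key for s in restrictions
                    if s is not None and not s.is_trivial}
    assert {s.key for s in splits_of(pruned)} == restrictions


class TestDerootReroot:
    def test_deroot_bifurcating_root(self, quartet_ab_cd):
        d = deroot(quartet_ab_cd)
        assert not d.rooted
        assert len(d.root.children) == 3
        assert splits_of(d) == splits_of(quartet_ab_cd)

    def test_deroot_idempotent(self):
        t = parse_newick("(A,B,(C,D));")
        assert splits_of(deroot(t)) == splits_of(t)
        assert not deroot(t).rooted

    def test_deroot_two_leaves_errors(self):
        with pytest.raises(TreeError):
            deroot(parse_newick("(A,B);"))

    def test_reroot_on_split(self, quartet_ab_cd):
        r = reroot(quartet_ab_cd, {"C", "D"})
        assert r.rooted
        assert splits_of(r) == splits_of(quartet_ab_cd)
        clades = [frozenset(_leaves(c)) for c in r.root.children]
        assert frozenset("CD") in clades

    def test_reroot_on_single_leaf_always_valid(self, quartet_ab_cd):
        r = reroot(quartet_ab_cd, {"A"})
        clades = [frozenset(_leaves(c)) for c in r.root.children]
        assert frozenset("A") in clades
        assert splits_of(r) == splits_of(quartet_ab_cd)

    def test_reroot_non_split_errors(self, quartet_ab_cd):
        with pytest.raises(TreeError, match="monophyletic"):
            reroot(quartet_ab_cd, {"A", "C"})

    def test_reroot_all_leaves_errors(self, quartet_ab_cd):
        with pytest.raises(TreeError):
            reroot(quartet_ab_cd, quartet_ab_cd.taxa)


def _leaves(node):
    if node.is_leaf:
        return [node.label]
    return [l for c in node.children for l in _leaves(c)]


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(0, 10**6))
def test_deroot_reroot_conserve_split_set(seed):
    rng = random.Random(seed)
    n = rng.randint(4, 12)
    taxa = [f"t{i}" for i in range(n)]
    from mlsupertree import random_binary_tree
    tree = random_binary_tree(taxa, rng)
    out = rng.sample(taxa, 1)
    assert splits_of(reroot(tree, out)) == splits_of(tree)
    assert splits_of(deroot(tree)) == splits_of(tree)


class TestTreeFiles:
    def test_newick_file_order_and_blank_lines(self, tmp_path):
        p = tmp_path / "trees.nwk"
        p.write_text("((A,B),C);\n\n((A,C),B);\n(A,(B,C));\n")
        ts = parse_tree_file(p)
        assert len(ts) == 3
        assert [sorted(t.taxa) for t in ts] == [["A", "B", "C"]] * 3

    def test_malformed_line_reported_with_number(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A,B),C);\n((A,B;\n")
        with pytest.raises(TreeError, match="line 2"):
            parse_tree_file(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.nwk"
        p.write_text("\n\n")
        with pytest.raises(TreeError):
            parse_tree_file(p)

    def test_nexus_translate_table_resolved(self, tmp_path):
        p = tmp_path / "trees.nex"
        p.write_text(
            "#NEXUS\nbegin trees;\n"
            "translate 1 human, 2 mouse, 3 elephant, 4 armadillo;\n"
            "tree one = ((1,2),(3,4));\n"
            "tree two = ((1,3),(2,4));\n"
            "end;\n")
        ts = parse_tree_file(p, format="nexus")
        assert len(ts) == 2
        assert ts.union_taxa == {"human", "mouse", "elephant", "armadillo"}
        assert splits_of(ts[0]) == splits_of(
            parse_newick("((human,mouse),(elephant,armadillo));"))

    def test_union_taxa_and_order_preserved(self):
        trees = [parse_newick("((A,B),C);"), parse_newick("((B,C),D);")]
        ts = InputTreeSet(trees)
        assert ts.union_taxa == frozenset("ABCD")
        assert ts[0] is trees[0] and ts[1] is trees[1]
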