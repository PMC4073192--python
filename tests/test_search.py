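"""Stepwise-addition starts, SPR neighborhoods and the four hill-climbing
strategies, checked against an exhaustive-enumeration oracle on small
instances."""

import itertools
import random

import pytest

from mlsupertree import (InputTreeSet, SearchConfig, SteelRodrigoModel,
                         TreeError, exhaustive_ml_supertree,
                         n_unrooted_topologies, parse_newick, prune_to_taxa,
                         random_binary_tree, robinson_foulds, run_search,
                         score_supertree, splits_of, spr_neighbors,
                         stepwise_addition_start)
from mlsupertree.search import enumerate_topologies


class TestStepwiseAddition:
    def test_three_taxa_unique_topology(self):
        inputs = InputTreeSet([parse_newick("((A,B),(C,D));")])
        t = stepwise_addition_start("ABC", inputs, rng=random.Random(0))
        assert t.taxa == frozenset("ABC")

    def test_consistent_signal_gives_perfect_start(self):
        """With a single binary tree on all taxa as the only signal, greedy
        insertion reaches d=0 for every insertion order (checked over many
        seeds on 5 taxa)."""
        full = parse_newick("(((A,B),C),(D,E));")
        inputs = InputTreeSet([full])
        for seed in range(30):
            t = stepwise_addition_start(full.taxa, inputs,
                                        rng=random.Random(seed))
            assert robinson_foulds(t, full) == 0

    def test_determinism(self, conflict_free_instance):
        truth, inputs, _ = conflict_free_instance
        t1 = stepwise_addition_start(inputs.union_taxa, inputs,
                                     rng=random.Random(123))
        t2 = stepwise_addition_start(inputs.union_taxa, inputs,
                                     rng=random.Random(123))
        assert splits_of(t1) == splits_of(t2)

    def test_too_few_taxa(self):
        inputs = InputTreeSet([parse_newick("((A,B),(C,D));")])
        with pytest.raises(TreeError):
            stepwise_addition_start("AB", inputs, rng=random.Random(0))


class TestSprNeighbors:
    def test_quartet_reaches_both_other_topologies(self, quartet_ab_cd):
        nbrs = list(spr_neighbors(quartet_ab_cd))
        keys = [splits_of(t) for t in nbrs]
        assert len(nbrs) == 2
        expected = [splits_of(parse_newick("((A,C),(B,D));")),
                    splits_of(parse_newick("((A,D),(B,C));"))]
        assert all(e in keys for e in expected)

    def test_neighbors_differ_by_rf_at_least_two(self):
        t = random_binary_tree("ABCDEFG", random.Random(2))
        for nbr in spr_neighbors(t):
            assert nbr.taxa == t.taxa
            assert robinson_foulds(t, nbr) >= 2

    def test_five_leaf_neighborhood_matches_exhaustive_oracle(self):
        """Brute-force oracle over all 15 five-leaf topologies: T' is an
        SPR neighbor of T iff, for some prunable side S of T, both trees
        agree when restricted to S and when restricted to its complement
        (detach S unchanged, reattach anywhere else)."""
        t = parse_newick("(((A,B),C),(D,E));")
        got = {frozenset(s.key for s in splits_of(n))
               for n in spr_neighbors(t)}
        sides = {frozenset((x,)) for x in t.taxa}
        sides |= {t.taxa - frozenset((x,)) for x in t.taxa}
        for s in splits_of(t):
            sides |= {s.side_a, s.side_b}
        reachable = set()
        for cand in enumerate_topologies("ABCDE"):
            if robinson_foulds(cand, t) == 0:
                continue
            from mlsupertree import Split
            for side in sides:
                comp = t.taxa - side
                # the pruned subtree survives as a clade of the neighbor
                if 2 <= len(side) <= len(t.taxa) - 2 and \
                        Split(side, comp) not in splits_of(cand):
                    continue
                same_outside = (len(comp) < 2 or robinson_foulds(
                    prune_to_taxa(cand, comp), prune_to_taxa(t, comp)) == 0)
                # the pruned subtree keeps its rooted shape: adding one
                # complement leaf marks the attachment point on both trees
                marked = side | {min(comp)}
                same_inside = robinson_foulds(
                    prune_to_taxa(cand, marked), prune_to_taxa(t, marked)) == 0
                if same_outside and same_inside:
                    reachable.add(frozenset(s.key for s in splits_of(cand)))
                    break
        assert got == reachable

    def test_non_binary_input_rejected(self):
        with pytest.raises(TreeError):
            list(spr_neighbors(parse_newick("(A,B,C,D,E);")))

    def test_original_topology_never_yielded(self):
        t = random_binary_tree("ABCDEF", random.Random(3))
        for nbr in spr_neighbors(t):
            assert splits_of(nbr) != splits_of(t)


class TestEnumeration:
    def test_topology_counts(self):
        assert n_unrooted_topologies(4) == 3
        assert n_unrooted_topologies(6) == 105
        assert n_unrooted_topologies(8) == 10395
        assert sum(1 for _ in enumerate_topologies("ABCDEF")) == 105

    def test_enumerated_topologies_are_distinct(self):
        seen = {frozenset(s.key for s in splits_of(t))
                for t in enumerate_topologies("ABCDE")}
        assert len(seen) == 15


class TestExhaustive:
    def test_single_quartet_input(self, quartet_ab_cd):
        inputs = InputTreeSet([quartet_ab_cd])
        best, bd = exhaustive_ml_supertree(inputs)
        assert bd.total_log_likelihood == 0.0
        assert splits_of(best) == splits_of(quartet_ab_cd)

    def test_too_many_taxa_rejected(self):
        t = random_binary_tree("ABCDEFGHI", random.Random(0))
        with pytest.raises(TreeError, match="run_search"):
            exhaustive_ml_supertree(InputTreeSet([t]))

    def test_co_optima_reported(self, quartet_ab_cd):
        # a single 4-taxon input on a 5-taxon union leaves freedom: several
        # 5-leaf topologies restrict to AB|CD
        inputs = InputTreeSet([quartet_ab_cd, parse_newick("((A,B),(C,E));")])
        best, bd, co = exhaustive_ml_supertree(inputs, return_all=True)
        assert bd.total_log_likelihood == 0.0
        assert len(co) >= 2
        for t in co:
            assert score_supertree(t, inputs).total_log_likelihood == 0.0


class TestRunSearch:
    def test_defaults_mirror_reference_protocol(self):
        cfg = SearchConfig()
        assert cfg.strategy == 4
        assert cfg.max_iterations == 10

    @pytest.mark.parametrize("strategy", [1, 2, 3, 4])
    def test_trajectory_monotone_and_terminates(self, strategy,
                                                conflict_free_instance):
        truth, inputs, _ = conflict_free_instance
        res = run_search(inputs, config=SearchConfig(
            strategy=strategy, seed=strategy * 11, n_restarts=2))
        totals = [t for _, t in res.trajectory]
        assert all(b >= a for a, b in zip(totals, totals[1:]))
        assert res.best_score.total_log_likelihood == \
            score_supertree(res.best_tree, inputs).total_log_likelihood

    def test_conflict_free_recovery_strategy_1(self, conflict_free_instance):
        truth, inputs, _ = conflict_free_instance
        res = run_search(inputs, config=SearchConfig(
            strategy=1, n_restarts=5, seed=0))
        assert res.best_score.total_log_likelihood == 0.0
        assert splits_of(res.best_tree) == splits_of(truth)

    def test_start_tree_used_and_validated(self, conflict_free_instance):
        truth, inputs, _ = conflict_free_instance
        res = run_search(inputs, config=SearchConfig(
            strategy=1, seed=0, start_tree=truth))
        assert res.best_score.total_log_likelihood == 0.0
        bad = parse_newick("((A,B),(C,D));")
        with pytest.raises(TreeError, match="missing"):
            run_search(inputs, config=SearchConfig(start_tree=bad))

    def test_polytomous_start_resolved_with_warning(self,
                                                    conflict_free_instance):
        truth, inputs, _ = conflict_free_instance
        star = parse_newick("(" + ",".join(sorted(truth.taxa)) + ");")
        with pytest.warns(UserWarning, match="polytomies"):
            res = run_search(inputs, config=SearchConfig(
                strategy=1, seed=1, start_tree=star))
        assert res.best_tree.taxa == truth.taxa

    def test_same_seed_same_result(self, conflict_free_instance):
        truth, inputs, _ = conflict_free_instance
        cfg = dict(strategy=2, seed=77, n_restarts=2)
        r1 = run_search(inputs, config=SearchConfig(**cfg))
        r2 = run_search(inputs, config=SearchConfig(**cfg))
        assert splits_of(r1.best_tree) == splits_of(r2.best_tree)
        assert r1.trajectory == r2.trajectory

    def test_heuristic_never_beats_exhaustive(self):
        rng = random.Random(31)
        truth = random_binary_tree("ABCDEF", rng)
        trees = []
        for _ in range(12):
            sub = rng.sample(sorted(truth.taxa), rng.randint(4, 6))
            trees.append(random_binary_tree(sub, rng))
        inputs = InputTreeSet(trees)
        _, best = exhaustive_ml_supertree(inputs)
        for strategy in (1, 2, 3, 4):
            res = run_search(inputs, config=SearchConfig(
                strategy=strategy, seed=5, n_restarts=3))
            assert res.best_score.total_log_likelihood <= \
                best.total_log_likelihood + 1e-9
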