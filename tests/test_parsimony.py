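"""Parsimony scoring and search, checked against brute-force oracles."""

import pytest

from conftest import brute_force_length, random_binary_tree, random_matrix
from pseudoext.matrix_io import CharacterMatrix
from pseudoext.parsimony import (
    SearchConfig,
    branch_swap_search,
    enumerate_topologies,
    exhaustive_search,
    fitch_length,
    heuristic_search,
    random_addition_build,
)
from pseudoext.treespace import (
    is_refinement_of,
    parse_newick,
    robinson_foulds,
    to_newick,
    unrooted_splits,
)


class TestFitchLength:
    def test_uniform_characters_cost_nothing(self):
        t = parse_newick("((A,B),(C,D));")
        m = CharacterMatrix(list("ABCD"), [["0", "1"]] * 4)
        assert fitch_length(t, m) == 0

    def test_conflicting_character_costs_two(self):
        # states 0,1,0,1 on ((A,B),(C,D)): two changes, verified by hand
        t = parse_newick("((A,B),(C,D));")
        m = CharacterMatrix(list("ABCD"), [["0"], ["1"], ["0"], ["1"]])
        assert fitch_length(t, m) == 2

    def test_rooting_invariance(self, rng):
        labels = [f"T{i}" for i in range(7)]
        m = random_matrix(labels, 10, 3, rng)
        t = random_binary_tree(labels, rng)
        from pseudoext.treespace import root_at

        lengths = {fitch_length(root_at(t, lab), m) for lab in labels[:4]}
        lengths.add(fitch_length(t, m))
        assert len(lengths) == 1

    @pytest.mark.parametrize("n_tips,k", [(4, 2), (5, 3), (6, 4)])
    def test_matches_assignment_enumeration(self, n_tips, k, rng):
        labels = [f"T{i}" for i in range(n_tips)]
        for _ in range(40):
            t = random_binary_tree(labels, rng)
            m = random_matrix(labels, 4, k, rng)
            assert fitch_length(t, m) == brute_force_length(t, m, k)

    def test_polytomies_scored_exactly(self, rng):
        labels = [f"T{i}" for i in range(6)]
        for _ in range(25):
            m = random_matrix(labels, 4, 3, rng)
            t = parse_newick("(T0,T1,T2,(T3,(T4,T5)));")
            assert fitch_length(t, m) == brute_force_length(t, m, 3)

    def test_missing_tip_never_costs_more_than_absent_tip(self, rng):
        labels = [f"T{i}" for i in range(6)]
        for _ in range(20):
            t = random_binary_tree(labels, rng)
            m = random_matrix(labels, 6, 3, rng, p_missing=0)
            cells = [["?"] * 6 if tx == "T5" else m.row(tx) for tx in labels]
            m2 = CharacterMatrix(labels, cells)
            reduced = t.copy()
            reduced.prune_taxa({"T5"})
            assert fitch_length(t, m2) <= fitch_length(reduced, m)

    def test_unscored_tip_rejected(self):
        t = parse_newick("((A,B),(C,D));")
        m = CharacterMatrix(list("ABC"), [["0"], ["1"], ["0"]])
        with pytest.raises(ValueError, match="no matrix row"):
            fitch_length(t, m)


class TestRandomAdditionBuild:
    def test_perfect_data_recovers_true_topology(self):
        # characters exactly mirror the splits of ((A,B),(C,D))
        m = CharacterMatrix(list("ABCD"),
                            [["0", "0"], ["0", "0"], ["1", "1"], ["1", "1"]])
        cfg = SearchConfig(seed=5)
        t = random_addition_build(m, cfg)
        assert unrooted_splits(t) == {frozenset({"C", "D"})} \
            or unrooted_splits(t) == {frozenset({"A", "B"})}
        assert fitch_length(t, m) == 2

    def test_constraint_forced_when_binary_on_all_taxa(self, rng):
        labels = list("ABCDX")
        m = random_matrix(labels, 8, 2, rng)
        cons = parse_newick("((A,B),(C,D));")
        for seed in range(5):
            t = random_addition_build(m, SearchConfig(seed=seed), cons)
            restricted = t.copy()
            restricted.prune_taxa({"X"})
            assert unrooted_splits(restricted) == unrooted_splits(cons)

    def test_same_seed_same_tree(self, rng):
        labels = [f"T{i}" for i in range(8)]
        m = random_matrix(labels, 10, 3, rng)
        t1 = random_addition_build(m, SearchConfig(seed=9))
        t2 = random_addition_build(m, SearchConfig(seed=9))
        assert to_newick(t1) == to_newick(t2)


class TestBranchSwap:
    def test_climb_from_global_optimum_stays_there(self, rng):
        labels = [f"T{i}" for i in range(5)]
        for _ in range(20):
            m = random_matrix(labels, 8, 3, rng)
            winners, best = exhaustive_search(m)
            trees, length = branch_swap_search(winners[0], m,
                                               SearchConfig(seed=1))
            assert length == best
            assert all(fitch_length(t, m) == best for t in trees)

    def test_multistart_escapes_single_climb_optima(self, rng):
        # a lone SPR climb can stall one step above the optimum; pooled
        # random-addition starts must not
        labels = [f"T{i}" for i in range(5)]
        for _ in range(20):
            m = random_matrix(labels, 8, 3, rng)
            _, best = exhaustive_search(m)
            res = heuristic_search(m, SearchConfig(n_addition_sequences=6,
                                                   seed=1))
            assert res.best_length == best

    def test_nni_connects_all_four_taxon_topologies(self, rng):
        labels = list("ABCD")
        m = random_matrix(labels, 10, 2, rng)
        _, best = exhaustive_search(m)
        cfg = SearchConfig(swapper="nni", seed=3)
        start = random_addition_build(m, cfg)
        _, length = branch_swap_search(start, m, cfg)
        assert length == best

    def test_never_longer_than_start(self, rng):
        labels = [f"T{i}" for i in range(7)]
        m = random_matrix(labels, 12, 4, rng)
        start = random_binary_tree(labels, rng)
        start_len = fitch_length(start, m)
        _, length = branch_swap_search(start, m, SearchConfig(seed=0))
        assert length <= start_len

    def test_constraint_violations_never_returned(self, rng):
        labels = [f"T{i}" for i in range(7)]
        m = random_matrix(labels, 10, 3, rng)
        cons = parse_newick("((T0,T1),(T2,T3));")
        start = random_addition_build(m, SearchConfig(seed=2), cons)
        trees, _ = branch_swap_search(start, m, SearchConfig(seed=2), cons)
        assert trees
        for t in trees:
            assert is_refinement_of(t, cons)


class TestHeuristicSearch:
    def test_six_taxa_matches_exhaustive(self, rng):
        labels = [f"T{i}" for i in range(6)]
        for _ in range(10):
            m = random_matrix(labels, 10, 3, rng)
            _, best = exhaustive_search(m)
            res = heuristic_search(m, SearchConfig(n_addition_sequences=5,
                                                   seed=4))
            assert res.best_length == best

    def test_all_missing_matrix_is_degenerate(self):
        labels = [f"T{i}" for i in range(6)]
        m = CharacterMatrix(labels, [["?"] * 5 for _ in labels])
        res = heuristic_search(m, SearchConfig(n_addition_sequences=2,
                                               trees_held_per_replicate=5,
                                               max_saved_trees=5, seed=0))
        assert res.best_length == 0
        assert len(res.trees) <= 5

    def test_constraint_never_shortens_optimum(self, rng):
        labels = [f"T{i}" for i in range(7)]
        cons = parse_newick("((T0,T1),(T2,T3),(T4,T5));")
        for _ in range(10):
            m = random_matrix(labels, 10, 3, rng)
            free = heuristic_search(m, SearchConfig(n_addition_sequences=3,
                                                    seed=6))
            constrained = heuristic_search(
                m, SearchConfig(n_addition_sequences=3, seed=6), cons)
            assert constrained.best_length >= free.best_length
            _, exact = exhaustive_search(m, cons)
            assert constrained.best_length == exact

    def test_full_binary_constraint_returns_it(self, rng):
        labels = [f"T{i}" for i in range(7)]
        m = random_matrix(labels, 10, 3, rng)
        cons = random_binary_tree(labels, rng)
        res = heuristic_search(m, SearchConfig(n_addition_sequences=2, seed=1),
                               cons)
        assert len(res.trees) == 1
        assert robinson_foulds(res.trees[0], cons) == 0

    def test_reproducible_for_fixed_seed(self, rng):
        labels = [f"T{i}" for i in range(8)]
        m = random_matrix(labels, 15, 3, rng)
        cfg = SearchConfig(n_addition_sequences=3, seed=77)
        r1 = heuristic_search(m, cfg)
        r2 = heuristic_search(m, cfg)
        assert r1.best_length == r2.best_length
        assert [to_newick(t) for t in r1.trees] == \
            [to_newick(t) for t in r2.trees]


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(4, 3), (5, 15), (6, 105)])
    def test_topology_counts(self, n, count):
        labels = [f"T{i}" for i in range(n)]
        trees = list(enumerate_topologies(labels))
        assert len(trees) == count
        keys = {frozenset(unrooted_splits(t)) for t in trees}
        assert len(keys) == count  # all distinct
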