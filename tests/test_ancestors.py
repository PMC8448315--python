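"""Ancestral-state reconstruction and HPA generation."""

import pytest

from conftest import brute_force_mpr, random_binary_tree, random_matrix
from pseudoext.ancestors import (
    fitch_mpr_sets,
    generate_hpas,
    mask_ambiguous,
    number_internal_nodes,
    repair_inapplicable,
)
from pseudoext.matrix_io import CharacterMatrix, DependencyMap
from pseudoext.parsimony import fitch_length
from pseudoext.synthetic_data import SimConfig, simulate_matrix
from pseudoext.treespace import parse_newick, root_at


class TestMprSets:
    def test_uniform_states_give_singleton_sets(self):
        t = parse_newick("((A,B),(C,D));", rooted=True)
        m = CharacterMatrix(list("ABCD"), [["0"]] * 4)
        at = fitch_mpr_sets(t, m)
        assert all(at.mpr[nid][0] == frozenset({"0"}) for nid in at.node_ids)

    def test_conflict_makes_root_ambiguous(self):
        # ((A:0,B:1),(C:0,D:1)): every internal node can be 0 or 1
        t = parse_newick("((A,B),(C,D));", rooted=True)
        m = CharacterMatrix(list("ABCD"), [["0"], ["1"], ["0"], ["1"]])
        at = fitch_mpr_sets(t, m)
        root_id = len(t) + 1
        assert at.mpr[root_id][0] == frozenset({"0", "1"})

    @pytest.mark.parametrize("n_tips,k", [(4, 2), (5, 3), (6, 3)])
    def test_matches_assignment_enumeration(self, n_tips, k, rng):
        labels = [f"T{i}" for i in range(n_tips)]
        for _ in range(30):
            t = root_at(random_binary_tree(labels, rng), labels[0])
            m = random_matrix(labels, 3, k, rng)
            at = fitch_mpr_sets(t, m)
            oracle = brute_force_mpr(t, m, k)
            for j in range(m.n_char):
                if not any(c.isdigit() for tx in labels
                           for c in m.row(tx)[j]):
                    continue  # nothing observed: reconstruction undefined
                for nid in at.node_ids:
                    assert at.mpr[nid][j] == oracle[j][nid], (
                        f"node {nid} char {j}"
                    )

    def test_polytomy_rejected(self):
        t = parse_newick("(A,B,C,D);", rooted=True)
        m = CharacterMatrix(list("ABCD"), [["0"]] * 4)
        with pytest.raises(ValueError, match="bifurcating"):
            fitch_mpr_sets(t, m)

    def test_node_numbering_is_preorder_from_ntips_plus_one(self):
        t = parse_newick("((A,B),(C,D));", rooted=True)
        ids = number_internal_nodes(t)
        assert sorted(ids) == [5, 6, 7]
        assert ids[5] is t.root


class TestMasking:
    def test_single_state_kept_ambiguity_masked(self):
        t = parse_newick("((A,B),(C,D));", rooted=True)
        m = CharacterMatrix(list("ABCD"),
                            [["0", "0"], ["1", "0"], ["0", "0"], ["1", "0"]])
        at = mask_ambiguous(fitch_mpr_sets(t, m))
        root_id = 5
        assert at.masked[root_id] == ["?", "0"]
        assert at.masked_cells == 3  # all three nodes ambiguous at char 1

    def test_masking_is_monotone_under_added_conflict(self, rng):
        # turning one more tip into a conflicting state never resolves a ?
        labels = [f"T{i}" for i in range(6)]
        for _ in range(15):
            t = root_at(random_binary_tree(labels, rng), labels[0])
            m = random_matrix(labels, 4, 2, rng, p_missing=0, p_inapplicable=0)
            at1 = mask_ambiguous(fitch_mpr_sets(t, m))
            cells = [list(r) for r in m.cells]
            row = int(rng.integers(len(labels)))
            col = int(rng.integers(m.n_char))
            cells[row][col] = "1" if cells[row][col] == "0" else "0"
            at2 = mask_ambiguous(fitch_mpr_sets(
                t, CharacterMatrix(labels, cells)))
            for nid in at1.node_ids:
                for j in range(m.n_char):
                    if j == col:
                        continue
                    if at1.masked[nid][j] == "?":
                        # unrelated characters unaffected; flipped column may
                        # change either way
                        assert at2.masked[nid][j] == at1.masked[nid][j]


class TestRepair:
    @pytest.fixture
    def table(self):
        t = parse_newick("((A,B),(C,D));", rooted=True)
        m = CharacterMatrix(
            list("ABCD"),
            [["0", "2", "1"], ["0", "2", "1"], ["0", "2", "1"], ["0", "2", "1"]],
        )
        return mask_ambiguous(fitch_mpr_sets(t, m))

    def test_trigger_state_masks_dependent(self, table):
        dep = DependencyMap(((1, frozenset({"0"}), 2),))
        out = repair_inapplicable(table, dep)
        for nid in out.node_ids:
            assert out.masked[nid][1] == "?"
            assert out.masked[nid][0] == "0"
        assert out.repaired_cells == len(out.node_ids)

    def test_unknown_controller_masks_dependent(self):
        t = parse_newick("((A,B),(C,D));", rooted=True)
        m = CharacterMatrix(list("ABCD"),
                            [["0", "2"], ["1", "2"], ["0", "2"], ["1", "2"]])
        at = mask_ambiguous(fitch_mpr_sets(t, m))
        dep = DependencyMap(((1, frozenset({"9"}), 2),))
        out = repair_inapplicable(at, dep)
        for nid in out.node_ids:
            assert out.masked[nid][0] == "?"  # ambiguous controller
            assert out.masked[nid][1] == "?"  # conservatively repaired

    def test_chained_dependencies_reach_fixed_point(self, table):
        dep = DependencyMap(((1, frozenset({"0"}), 2),
                             (2, frozenset({"2"}), 3)))
        out = repair_inapplicable(table, dep)
        for nid in out.node_ids:
            # char 2 repaired to ?, which then repairs char 3
            assert out.masked[nid][1] == "?"
            assert out.masked[nid][2] == "?"

    def test_empty_map_is_identity(self, table):
        out = repair_inapplicable(table, DependencyMap())
        assert out.masked == table.masked
        assert out.repaired_cells == 0

    def test_cyclic_map_rejected(self, table):
        dep = DependencyMap(((1, frozenset({"0"}), 2),
                             (2, frozenset({"0"}), 1)))
        with pytest.raises(ValueError, match="cyclic"):
            repair_inapplicable(table, dep)


class TestGenerateHpas:
    @pytest.fixture
    def sim(self):
        tree = parse_newick(
            "(((A:.04,B:.04):.04,(C:.04,D:.04):.04):.04,"
            "((E:.04,F:.04):.04,(G:.04,H:.04):.04):.04);", rooted=True)
        return simulate_matrix(SimConfig(tree=tree, n_char=120, n_states=3,
                                         soft_fraction=0.0, seed=42))

    def test_row_count_is_tips_minus_one(self, sim):
        hpas, table, pruned = generate_hpas(sim.tree, sim.matrix)
        assert len(hpas.taxa) == len(sim.tree) - 1
        assert all(label.startswith("HPA_") for label in hpas.taxa)

    def test_dropping_a_pair_loses_two_rows(self, sim):
        hpas, _, pruned = generate_hpas(sim.tree, sim.matrix,
                                        drop_order={"A", "B"})
        assert len(pruned) == 6
        assert len(hpas.taxa) == 5

    def test_rows_use_only_observed_states(self, sim):
        hpas, _, _ = generate_hpas(sim.tree, sim.matrix)
        for j in range(1, sim.matrix.n_char + 1):
            observed = set(sim.matrix.column(j)) - {"?", "-"}
            for row in hpas.cells:
                assert row[j - 1] == "?" or row[j - 1] in observed

    def test_deterministic(self, sim):
        h1, _, _ = generate_hpas(sim.tree, sim.matrix, drop_order={"C"})
        h2, _, _ = generate_hpas(sim.tree, sim.matrix, drop_order={"C"})
        assert h1 == h2

    def test_homoplasy_free_recovery_of_true_states(self):
        # with zero homoplasy every unambiguous reconstruction must equal
        # the generating state
        tree = parse_newick(
            "(((A:.02,B:.02):.02,(C:.02,D:.02):.02):.02,"
            "((E:.02,F:.02):.02,(G:.02,H:.02):.02):.02);", rooted=True)
        sim = simulate_matrix(SimConfig(tree=tree, n_char=200, n_states=2,
                                        soft_fraction=0.0, seed=7))
        # homoplasy-free characters: the true change count equals the
        # parsimony length, so the true history is itself an MPR
        t = sim.tree
        true_changes = [0] * sim.matrix.n_char
        for node in t.preorder():
            if node.parent is None:
                continue
            diff = sim.node_states[node.label] != sim.node_states[node.parent.label]
            for j in diff.nonzero()[0]:
                true_changes[int(j)] += 1
        keep = [j for j in range(sim.matrix.n_char)
                if true_changes[j] == fitch_length(t, CharacterMatrix(
                    sim.matrix.taxa,
                    [[row[j]] for row in sim.matrix.cells]))]
        assert len(keep) > 50
        cells = [[row[j] for j in keep] for row in sim.matrix.cells]
        m = CharacterMatrix(sim.matrix.taxa, cells)
        hpas, table, pruned = generate_hpas(t, m)
        ids = number_internal_nodes(pruned)
        for nid in table.node_ids:
            truth = sim.node_states[str(nid)]
            for jj, j in enumerate(keep):
                symbol = table.masked[nid][jj]
                if symbol != "?":
                    assert symbol == str(int(truth[j]))

    def test_cherry_parent_within_one_step_of_children(self, sim):
        hpas, table, pruned = generate_hpas(sim.tree, sim.matrix)
        ids = number_internal_nodes(pruned)
        for nid, node in ids.items():
            kids = [c for c in node.children if c.is_leaf]
            if len(kids) != 2:
                continue
            for j in range(sim.matrix.n_char):
                symbol = table.masked[nid][j]
                if symbol == "?":
                    continue
                states = {sim.matrix.row(k.label)[j] for k in kids}
                # parent state must match at least one child (one Fitch step
                # from either child at most)
                assert symbol in states

    def test_too_small_pruned_tree_rejected(self, sim):
        with pytest.raises(ValueError, match="fewer than 3"):
            generate_hpas(sim.tree, sim.matrix,
                          drop_order={"A", "B", "C", "D", "E", "F"})
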