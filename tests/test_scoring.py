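"""Misplacement classification, RF aggregation, and category tallies."""

import pytest

from pseudoext.scoring import (
    TREATMENTS,
    CladeMap,
    MisplacementRecord,
    classify_placement,
    load_published_categories,
    load_published_rf,
    summarize_rf,
    tally_categories,
)
from pseudoext.treespace import parse_newick


@pytest.fixture
def cmap():
    # 8 placentals in 2-order superorders + 1 outgroup tip
    return CladeMap(
        orders={
            "OrdW": frozenset({"W1", "W2"}),
            "OrdX": frozenset({"X1"}),
            "OrdY": frozenset({"Y1", "Y2", "Y3"}),
            "OrdZ": frozenset({"Z1", "Z2"}),
        },
        superorders={
            "SupA": frozenset({"OrdW", "OrdX"}),
            "SupB": frozenset({"OrdY", "OrdZ"}),
        },
        outgroup_taxa=frozenset({"Out"}),
    )


@pytest.fixture
def msst():
    return parse_newick(
        "(Out,(((W1,W2),X1),((Y1,(Y2,Y3)),(Z1,Z2))));")


@pytest.fixture
def scaffold(msst):
    return msst.copy()


class TestClassifyPlacement:
    def test_scaffold_resolution_gets_no_categories(self, cmap, msst, scaffold):
        rec = classify_placement(msst.copy(), scaffold, msst, cmap,
                                 "OrdW", "Out")
        assert rec.categories == frozenset()

    def test_every_order_clean_on_the_msst_itself(self, cmap, msst, scaffold):
        for order in cmap.orders:
            rec = classify_placement(msst.copy(), scaffold, msst, cmap,
                                     order, "Out")
            assert rec.categories == frozenset(), order

    def test_order_moved_into_wrong_superorder_is_1_and_2(self, cmap, msst,
                                                          scaffold):
        # OrdW relocated inside SupB, next to the Z cherry
        inferred = parse_newick(
            "(Out,((X1,((Y1,(Y2,Y3)),((W1,W2),(Z1,Z2))))));")
        rec = classify_placement(inferred, scaffold, msst, cmap, "OrdW", "Out")
        assert rec.categories == frozenset({1, 2})

    def test_split_order_is_category_4(self, cmap, msst, scaffold):
        # W1 and W2 separated across the tree
        inferred = parse_newick(
            "(Out,((W1,X1),((Y1,(Y2,Y3)),((W2,Z1),Z2))));")
        rec = classify_placement(inferred, scaffold, msst, cmap, "OrdW", "Out")
        assert 4 in rec.categories
        assert 1 in rec.categories

    def test_internal_cherry_swap_is_category_5_only(self, cmap, msst,
                                                     scaffold):
        # OrdY monophyletic, attached correctly, internal topology rearranged
        inferred = parse_newick(
            "(Out,(((W1,W2),X1),((Y2,(Y1,Y3)),(Z1,Z2))));")
        rec = classify_placement(inferred, scaffold, msst, cmap, "OrdY", "Out")
        assert rec.categories == frozenset({5})

    def test_broken_other_superorder_is_category_3(self, cmap, msst, scaffold):
        # focal OrdY's superorder intact; SupA broken apart by the outgroup
        # of the placental radiation: move X1 out of SupA
        inferred = parse_newick(
            "(Out,((W1,W2),(X1,((Y1,(Y2,Y3)),(Z1,Z2)))));")
        rec = classify_placement(inferred, scaffold, msst, cmap, "OrdY", "Out")
        assert 3 in rec.categories
        assert 2 not in rec.categories

    def test_scaffold_polytomy_never_flags_congruent_resolution(self, cmap,
                                                                msst):
        # scaffold leaves SupB's orders unresolved; any resolution is clean
        poly_scaffold = parse_newick(
            "(Out,(((W1,W2),X1),(Y1,(Y2,Y3),(Z1,Z2))));")
        inferred = parse_newick(
            "(Out,(((W1,W2),X1),((Y1,(Y2,Y3)),(Z1,Z2))));")
        rec = classify_placement(inferred, poly_scaffold, msst, cmap,
                                 "OrdZ", "Out")
        assert 1 not in rec.categories

    def test_category5_excludes_1_and_4_structurally(self, cmap, msst,
                                                     scaffold):
        # classifier outputs: 5 only with monophyly and congruent attachment
        trees = [
            "(Out,(((W1,W2),X1),((Y2,(Y1,Y3)),(Z1,Z2))));",
            "(Out,((X1,((Y1,(Y2,Y3)),((W1,W2),(Z1,Z2))))));",
            "(Out,((W1,X1),((Y1,(Y2,Y3)),((W2,Z1),Z2))));",
        ]
        for nwk in trees:
            for order in cmap.orders:
                rec = classify_placement(parse_newick(nwk), scaffold, msst,
                                         cmap, order, "Out")
                if 5 in rec.categories:
                    assert 1 not in rec.categories
                    assert 4 not in rec.categories

    def test_small_orders_never_get_4_or_5(self, cmap, msst, scaffold):
        inferred = parse_newick(
            "(Out,((X1,((Y1,(Y2,Y3)),((W1,W2),(Z1,Z2))))));")
        rec = classify_placement(inferred, scaffold, msst, cmap, "OrdX", "Out")
        assert 4 not in rec.categories and 5 not in rec.categories

    def test_tip_mismatch_rejected(self, cmap, msst, scaffold):
        with pytest.raises(ValueError, match="tip set"):
            classify_placement(parse_newick("((W1,W2),(X1,Out));"),
                               scaffold, msst, cmap, "OrdW", "Out")


class TestSummarizeRF:
    def test_single_cell_mean_equals_median(self):
        s = summarize_rf({("O1", "scaffold"): [6]})
        assert s.row_mean["O1"] == 6 == s.row_median["O1"]
        assert s.col_mean["scaffold"] == 6 == s.col_median["scaffold"]

    def test_multi_tree_cells_average_first(self):
        cells = {
            ("O1", "scaffold"): [0, 2],       # cell value 1
            ("O1", "fossils"): [4],
            ("O2", "scaffold"): [2],
            ("O2", "fossils"): [10, 10, 10],  # cell value 10
        }
        s = summarize_rf(cells)
        assert s.cell_values[("O1", "scaffold")] == 1
        assert s.row_mean["O1"] == 2.5
        assert s.col_mean["fossils"] == 7.0
        assert s.col_median["scaffold"] == 1.5

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty cell"):
            summarize_rf({("O1", "scaffold"): []})

    def test_rounding_is_half_up_to_two_decimals(self):
        # 14.145 rounds up, not to even
        s = summarize_rf({("O1", "scaffold"): [14.145]})
        assert s.row_mean["O1"] == 14.15

    def test_tsv_output_is_byte_stable(self, tmp_path):
        cells = {("O1", "scaffold"): [0, 2], ("O1", "fossils"): [4]}
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        summarize_rf(cells).to_tsv(str(p1))
        summarize_rf(cells).to_tsv(str(p2))
        assert p1.read_bytes() == p2.read_bytes()


class TestTallyCategories:
    def test_row_totals_accumulate_across_treatments(self):
        recs = [MisplacementRecord("O1", t, frozenset({1, 2, 5}))
                for t in TREATMENTS]
        tally = tally_categories(recs)
        assert tally.row_counts["O1"] == {1: 7, 2: 7, 5: 7}

    def test_empty_records_count_as_congruent(self):
        recs = [MisplacementRecord("O1", t, frozenset()) for t in TREATMENTS]
        tally = tally_categories(recs)
        assert all(tally.congruent_per_treatment[t] == 1 for t in TREATMENTS)
        assert tally.never_category1 == ["O1"]

    def test_duplicate_record_rejected(self):
        recs = [MisplacementRecord("O1", "scaffold", frozenset()),
                MisplacementRecord("O1", "scaffold", frozenset({1}))]
        with pytest.raises(ValueError, match="duplicate"):
            tally_categories(recs)


class TestPublishedTables:
    """The shipped reference tables reproduce the published aggregates."""

    def test_rf_row_statistics(self):
        s = summarize_rf(load_published_rf())
        assert s.row_mean["Sirenia"] == 14.14
        assert s.row_median["Sirenia"] == 1
        assert s.row_mean["Cetartiodactyla"] == 22.86
        assert s.row_median["Cetartiodactyla"] == 24
        assert s.row_mean["Tubulidentata"] == 21.9
        assert s.row_median["Tubulidentata"] == 14

    def test_rf_column_statistics(self):
        s = summarize_rf(load_published_rf())
        assert s.col_mean["scaffold"] == 5.58
        assert s.col_median["scaffold"] == 4
        assert s.col_mean["fossils+hpas"] == 27.49
        assert s.col_median["fossils+hpas"] == 30

    def test_headline_category_counts(self):
        tally = tally_categories(load_published_categories())
        assert tally.congruent_per_treatment["scaffold+fossils+hpas"] == 8
        assert tally.congruent_per_treatment["hpas"] == 4
        assert len(tally.always_category1) == 10
        assert sorted(tally.never_category1) == ["Proboscidea", "Sirenia"]
        assert tally.col_counts["fossils"][2] == 17
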