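"""ED/GE/EDGE scores and the grid-cell diversity maps with their conservation laws."""

import math

import numpy as np
import pandas as pd
import pytest

from cycadrisk import (
    MetricsError,
    OccurrenceMatrix,
    edge_scores,
    fair_proportion_ed,
    faith_pd,
    ge_code,
    grid_mean_edge,
    grid_pd,
    grid_sr,
    parse_newick,
    percent_pd_lost,
    phylogenetic_endemism,
    weighted_endemism,
)


class TestFaithPD:
    @pytest.mark.parametrize(
        "subset,expected",
        [({"A", "B", "C"}, 5.0), ({"A", "B"}, 3.0), ({"A"}, 2.0), ({"C"}, 2.0)],
    )
    def test_worked_examples(self, toy_tree, subset, expected):
        assert faith_pd(toy_tree, subset) == pytest.approx(expected)

    def test_empty_subset_rejected(self, toy_tree):
        with pytest.raises(MetricsError, match="empty"):
            faith_pd(toy_tree, set())

    def test_monotone_under_inclusion(self, small_dataset):
        tree = small_dataset["tree"]
        tips = tree.tip_labels
        rng = np.random.default_rng(1)
        sub = set(rng.choice(tips, size=10, replace=False))
        sup = sub | set(rng.choice(tips, size=10, replace=False))
        assert faith_pd(tree, sub) <= faith_pd(tree, sup) + 1e-12


class TestFairProportion:
    def test_worked_example(self, toy_tree):
        ed = fair_proportion_ed(toy_tree)
        assert ed["A"] == pytest.approx(1.5)
        assert ed["B"] == pytest.approx(1.5)
        assert ed["C"] == pytest.approx(2.0)
        assert ed.sum() == pytest.approx(5.0)

    def test_star_tree_symmetry(self):
        t = parse_newick("(A:3,B:3,C:3,D:3);")
        ed = fair_proportion_ed(t)
        np.testing.assert_allclose(ed.to_numpy(), 3.0)

    def test_conservation_on_synthetic_tree(self, full_dataset):
        tree = full_dataset["tree"]
        ed = fair_proportion_ed(tree)
        assert ed.sum() == pytest.approx(tree.total_length, rel=1e-6)


class TestGE:
    @pytest.mark.parametrize(
        "cat,code", [("LC", 0), ("NT", 1), ("CD", 1), ("VU", 2), ("EN", 3), ("CR", 4)]
    )
    def test_fixed_coding(self, cat, code):
        assert ge_code(cat) == code

    def test_dd_excluded(self):
        with pytest.raises(MetricsError, match="excluded"):
            ge_code("DD")

    def test_unknown_category(self):
        with pytest.raises(MetricsError, match="VULNERABLE"):
            ge_code("VULNERABLE")


class TestEdgeScores:
    def test_formula_values(self):
        threats = pd.DataFrame(
            {"species": ["x", "y", "z"], "category": ["LC", "CR", "EN"]}
        )
        ed = {"x": 0.0, "y": math.e - 1.0, "z": 1.5}
        table = edge_scores(ed, threats).set_index("species")
        assert table.loc["x", "EDGE"] == pytest.approx(0.0)
        assert table.loc["y", "EDGE"] == pytest.approx(1.0 + 4 * math.log(2))
        assert table.loc["z", "EDGE"] == pytest.approx(
            math.log(2.5) + 3 * math.log(2)
        )

    def test_sorted_with_label_tiebreak(self):
        threats = pd.DataFrame(
            {"species": ["b", "a", "c"], "category": ["VU", "VU", "CR"]}
        )
        table = edge_scores({"a": 1.0, "b": 1.0, "c": 1.0}, threats)
        assert list(table["species"]) == ["c", "a", "b"]
        assert list(table["rank"]) == [1, 2, 3]

    def test_dd_rows_absent_and_missing_ed_rejected(self):
        threats = pd.DataFrame(
            {"species": ["x", "y"], "category": ["DD", "LC"]}
        )
        table = edge_scores({"y": 1.0}, threats)
        assert list(table["species"]) == ["y"]
        with pytest.raises(MetricsError, match="missing ED"):
            edge_scores({}, threats)

    def test_edge_strictly_increasing_in_ed_and_ge(self):
        threats = pd.DataFrame(
            {"species": ["a", "b", "c"], "category": ["VU", "VU", "EN"]}
        )
        t = edge_scores({"a": 1.0, "b": 2.0, "c": 1.0}, threats).set_index("species")
        assert t.loc["b", "EDGE"] > t.loc["a", "EDGE"]
        assert t.loc["c", "EDGE"] > t.loc["a", "EDGE"]


def test_percent_pd_lost_printed_totals():
    # the ~53% headline arises from remaining = total - threatened share
    total, lost = 8.8421e9, 4.7039e9
    pct = percent_pd_lost(total - lost, total)
    assert round(pct) == 53


class TestGridMetrics:
    def test_sr_counts(self, toy_occ):
        sr = grid_sr(toy_occ)
        assert sr.to_dict() == {1: 2, 2: 2, 3: 1}

    def test_pd_per_cell(self, toy_tree, toy_occ):
        pdm = grid_pd(toy_tree, toy_occ)
        assert pdm[1] == pytest.approx(3.0)   # {A, B}
        assert pdm[3] == pytest.approx(2.0)   # {C}
        assert (pdm <= toy_tree.total_length + 1e-12).all()

    def test_missing_species_listed(self, toy_tree):
        occ = OccurrenceMatrix.from_records([("A", 1), ("Z", 2)])
        with pytest.raises(MetricsError, match="Z"):
            grid_pd(toy_tree, occ)

    def test_weighted_endemism_worked_example(self, toy_occ):
        we, cwe = weighted_endemism(toy_occ)
        assert we.to_dict() == pytest.approx({1: 1.5, 2: 1.0, 3: 0.5})
        assert cwe[1] == pytest.approx(0.75)
        assert we.sum() == pytest.approx(3.0)

    def test_single_cell_endemic(self):
        occ = OccurrenceMatrix.from_records([("A", 7)])
        we, cwe = weighted_endemism(occ)
        assert we[7] == pytest.approx(1.0)
        assert cwe[7] == pytest.approx(1.0)

    def test_pe_worked_example(self, toy_tree, toy_occ):
        pe = phylogenetic_endemism(toy_tree, toy_occ)
        assert pe.to_dict() == pytest.approx({1: 2.0, 2: 2.0, 3: 1.0})
        assert pe.sum() == pytest.approx(5.0)

    def test_pe_all_in_one_cell_equals_total_pd(self, toy_tree):
        occ = OccurrenceMatrix.from_records([("A", 0), ("B", 0), ("C", 0)])
        pe = phylogenetic_endemism(toy_tree, occ)
        assert pe[0] == pytest.approx(toy_tree.total_length)

    def test_pe_bounded_by_pd_everywhere(self, small_dataset):
        tree, occ = small_dataset["tree"], small_dataset["occurrences"]
        pe = phylogenetic_endemism(tree, occ)
        pdm = grid_pd(tree, occ)
        assert (pe <= pdm + 1e-9).all()

    def test_conservation_laws_on_synthetic_run(self, full_dataset):
        tree, occ = full_dataset["tree"], full_dataset["occurrences"]
        we, _ = weighted_endemism(occ)
        pe = phylogenetic_endemism(tree, occ)
        assert we.sum() == pytest.approx(occ.n_species, rel=1e-6)
        assert pe.sum() == pytest.approx(tree.total_length, rel=1e-6)

    def test_mean_edge_ignores_dd(self, toy_tree, toy_occ):
        threats = pd.DataFrame(
            {"species": ["A", "B", "C"], "category": ["VU", "EN", "DD"]}
        )
        table = edge_scores(fair_proportion_ed(toy_tree), threats)
        me = grid_mean_edge(table, toy_occ)
        scores = table.set_index("species")["EDGE"]
        assert me[1] == pytest.approx((scores["A"] + scores["B"]) / 2)
        assert me[2] == pytest.approx(scores["A"])  # C is DD, ignored
        assert 3 not in me.index                    # only DD present there
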