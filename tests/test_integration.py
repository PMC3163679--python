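"""Set overlap, 2×2 association, correlation and clustering."""

import numpy as np
import pandas as pd
import pytest

from decaykit import integration as it
from decaykit.io import load_table1_fixture
from _linkage_oracle import brute_force_average_linkage


class TestIntersectGeneSets:
    def test_simple_overlap(self):
        universe = [f"G{i}" for i in range(10)]
        ov = it.intersect_gene_sets(["G0", "G1", "G2"], ["G1", "G2", "G3"],
                                    universe)
        assert ov.members_overlap == ("G1", "G2")
        assert ov.n_overlap == 2
        assert ov.n_universe == 10

    def test_disjoint_sets(self):
        ov = it.intersect_gene_sets(["A"], ["B"], ["A", "B", "C"])
        assert ov.n_overlap == 0

    def test_symmetry_in_set_order(self):
        u = [f"G{i}" for i in range(20)]
        a, b = u[:8], u[5:12]
        ov1 = it.intersect_gene_sets(a, b, u)
        ov2 = it.intersect_gene_sets(b, a, u)
        assert ov1.n_overlap == ov2.n_overlap
        assert ov1.members_overlap == ov2.members_overlap

    def test_reference_table_self_overlap(self):
        # the published table lists 61 records; one locus is printed
        # twice, so the id *set* has 60 members
        fx = load_table1_fixture()
        assert len(fx.records) == 61
        ov = it.intersect_gene_sets(fx.loci, fx.loci, fx.loci)
        assert ov.n_overlap == 60

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError):
            it.intersect_gene_sets(["A"], ["A"], [])

    def test_out_of_universe_members_clipped(self):
        ov = it.intersect_gene_sets(["A", "X"], ["A", "Y"], ["A", "B"])
        assert ov.n_set_a == ov.n_set_b == 1
        assert ov.members_overlap == ("A",)


def _chi2_closed_form(table):
    (a, b), (c, d) = np.asarray(table, dtype=float)
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestChiSquareAssociation:
    def test_independence_gives_zero(self):
        res = it.chi_square_association(np.array([[10, 10], [10, 10]]))
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_hand_computed_statistic(self):
        res = it.chi_square_association(np.array([[20, 10], [10, 20]]))
        assert res.chi_square == pytest.approx(6.6667, abs=1e-4)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError):
            it.chi_square_association(np.array([[0, 0], [5, 5]]))

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            t = rng.integers(1, 500, size=(2, 2))
            res = it.chi_square_association(t)
            assert res.chi_square == pytest.approx(
                _chi2_closed_form(t), rel=1e-10)

    def test_overlap_result_table_margins(self):
        u = [f"G{i}" for i in range(100)]
        ov = it.intersect_gene_sets(u[:30], u[20:50], u)
        assert ov.table.sum() == 100
        res = it.chi_square_association(ov)
        assert 0 <= res.p_value <= 1


class TestCorrelateExpressionDecay:
    def test_perfect_antimonotone_spearman(self):
        r = it.correlate_expression_decay(
            {"a": 1.0, "b": 2.0, "c": 3.0}, {"a": 3.0, "b": 2.0, "c": 1.0},
            method="spearman")
        assert r.rho == pytest.approx(-1.0)

    def test_self_correlation_is_one(self):
        v = {"a": 0.3, "b": -1.0, "c": 2.0, "d": 0.1}
        r = it.correlate_expression_decay(v, v, method="pearson")
        assert r.rho == pytest.approx(1.0)

    def test_pearson_against_direct_formula(self):
        e = np.array([0.1, -1.2, -2.0, -0.5])
        k = np.array([0.01, 0.03, 0.04, 0.02])
        expected = np.corrcoef(e, k)[0, 1]
        r = it.correlate_expression_decay(
            dict(zip("abcd", e)), dict(zip("abcd", k)), method="pearson")
        assert r.rho == pytest.approx(expected, rel=1e-12)
        assert r.rho < -0.9

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError):
            it.correlate_expression_decay(
                {"a": 1.0, "b": 1.0, "c": 1.0}, {"a": 1.0, "b": 2.0, "c": 3.0})

    def test_censored_values_are_dropped(self):
        r = it.correlate_expression_decay(
            {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0},
            {"a": 4.0, "b": 3.0, "c": 2.0, "d": np.inf})
        assert r.n == 3


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero_height(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                          [3.0, -1.0, 0.5]], index=["g1", "g2", "g3"])
        res = it.hierarchical_cluster(m)
        first = res.merge_tree[0]
        assert set(first[:2]) == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_have_distance_two(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
                         index=["g1", "g2"])
        d = it.correlation_distance_matrix(m)
        assert d[0] == pytest.approx(2.0)

    def test_matches_exhaustive_average_linkage_at_n4(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            m = pd.DataFrame(rng.normal(size=(4, 6)),
                             index=[f"g{i}" for i in range(4)])
            from scipy.spatial.distance import squareform

            dist = squareform(it.correlation_distance_matrix(m))
            expected = brute_force_average_linkage(dist)
            res = it.hierarchical_cluster(m)
            for (ei, ej, eh), (ai, aj, ah) in zip(expected, res.merge_tree):
                assert {ei, ej} == {ai, aj}
                assert ah == pytest.approx(eh, rel=1e-9)

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(10, 5)))
        res = it.hierarchical_cluster(m)
        heights = [h for _, _, h in res.merge_tree]
        assert heights == sorted(heights)

    def test_zero_variance_row_dropped(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0],
                          [0.0, 1.0, 0.0]], index=["flat", "a", "b"])
        res = it.hierarchical_cluster(m)
        assert "flat" not in res.leaf_order
        assert len(res.leaf_order) == 2

    def test_ordered_matrix_is_clipped_for_display(self):
        m = pd.DataFrame([[5.0, -8.0, 0.0], [1.0, 2.0, 3.0]],
                         index=["a", "b"])
        res = it.hierarchical_cluster(m)
        assert res.ordered_matrix.to_numpy().max() <= 3.0
        assert res.ordered_matrix.to_numpy().min() >= -3.0
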