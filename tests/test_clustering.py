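"""Distances, Lance–Williams agglomeration, cuts and contingency tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import linkage as scipy_linkage

from aorta_ssm.clustering import (
    LINKAGES,
    METRICS,
    ClusterAssignment,
    DistanceMatrix,
    agglomerate,
    cluster_contingency,
    cut_at_height,
    cut_to_k,
    dissimilarity_matrix,
    majority_cluster_fraction,
    to_newick,
)
from aorta_ssm.errors import InvalidParameterError, UndefinedCorrelationError

from oracles import naive_agglomerate, naive_pairwise


def three_object_distances() -> DistanceMatrix:
    """d(A,B)=1, d(A,C)=4, d(B,C)=5 — the hand-worked example."""
    D = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    return DistanceMatrix(D, "euclidean")


class TestDissimilarity:
    def test_identical_rows_correlation_zero(self):
        X = np.vstack([np.arange(6.0), np.arange(6.0), np.arange(6.0) * 2 + 1])
        D = dissimilarity_matrix(X, "correlation")
        assert D.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        # positive affine rescaling leaves correlation distance at 0 too
        assert D.values[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anti_correlated_rows_distance_two(self):
        v = np.array([1.0, -2.0, 3.0, 0.5])
        D = dissimilarity_matrix(np.vstack([v, -v]), "correlation")
        assert D.values[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_three_four_five_euclidean(self):
        X = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        D = dissimilarity_matrix(X, "euclidean")
        assert D.values[0, 1] == pytest.approx(5.0)

    @pytest.mark.parametrize("metric", METRICS)
    def test_matches_naive_double_loop(self, metric):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 10)) + 1.0
        cov = None
        if metric == "mahalanobis":
            A = rng.normal(size=(10, 10))
            cov = A @ A.T + 10 * np.eye(10)
        D = dissimilarity_matrix(X, metric, covariance=cov)
        expect = naive_pairwise(X, metric, covariance=cov)
        np.testing.assert_allclose(D.values, expect, atol=1e-12)

    def test_zero_variance_row_rejected_under_correlation(self):
        X = np.vstack([np.full(5, 2.0), np.arange(5.0)])
        with pytest.raises(UndefinedCorrelationError, match="0"):
            dissimilarity_matrix(X, "correlation")

    def test_mahalanobis_requires_positive_definite_covariance(self):
        X = np.random.default_rng(1).normal(size=(4, 3))
        with pytest.raises(InvalidParameterError):
            dissimilarity_matrix(X, "mahalanobis")
        with pytest.raises(InvalidParameterError):
            dissimilarity_matrix(X, "mahalanobis",
                                 covariance=np.zeros((3, 3)))


class TestAgglomerate:
    def test_hand_worked_wpgma(self):
        dend = agglomerate(three_object_distances(), "mcquitty")
        assert [m[:2] for m in dend.merges] == [(0, 1), (2, 3)]
        np.testing.assert_allclose(dend.heights, [1.0, 4.5])

    def test_hand_worked_single_and_complete(self):
        assert agglomerate(three_object_distances(), "single").heights[1] == 4.0
        assert agglomerate(three_object_distances(), "complete").heights[1] == 5.0

    @pytest.mark.parametrize("linkage", LINKAGES)
    def test_matches_naive_rescan_oracle(self, linkage):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            X = rng.normal(size=(n, 5))
            D = dissimilarity_matrix(X, "euclidean")
            ours = agglomerate(D, linkage)
            expect = naive_agglomerate(D.values, linkage)
            np.testing.assert_allclose(
                ours.heights, [h for _, _, h in expect], atol=1e-10
            )

    @pytest.mark.parametrize("method,link", [
        ("single", "single"), ("complete", "complete"),
        ("average", "average"), ("weighted", "mcquitty"),
    ])
    def test_matches_scipy_heights_on_continuous_data(self, method, link):
        # scipy implements these four linkages with the same semantics on a
        # precomputed condensed distance matrix; ties have measure zero here
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 6))
        D = dissimilarity_matrix(X, "euclidean")
        ours = agglomerate(D, link)
        Z = scipy_linkage(squareform(D.values), method=method)
        np.testing.assert_allclose(np.sort(ours.heights), np.sort(Z[:, 2]),
                                   atol=1e-10)

    def test_ultrametric_recovered_exactly(self):
        # an ultrametric distance: two tight pairs at 1, joined at 6
        D = np.array([
            [0, 1, 6, 6],
            [1, 0, 6, 6],
            [6, 6, 0, 1],
            [6, 6, 1, 0],
        ], dtype=float)
        for link in ("single", "complete", "average", "mcquitty"):
            dend = agglomerate(DistanceMatrix(D, "euclidean"), link)
            np.testing.assert_allclose(np.sort(dend.heights), [1, 1, 6])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.5, 3.0), st.floats(-5.0, 5.0))
    def test_correlation_clustering_scale_invariant(self, seed, a, b):
        # replacing a row v by a*v + b (a > 0) changes nothing downstream
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(7, 9))
        Y = X.copy()
        Y[3] = a * Y[3] + b
        d1 = dissimilarity_matrix(X, "correlation")
        d2 = dissimilarity_matrix(Y, "correlation")
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-9)
        h1 = agglomerate(d1, "mcquitty").heights
        h2 = agglomerate(d2, "mcquitty").heights
        np.testing.assert_allclose(h1, h2, atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 6))
        perm = rng.permutation(8)
        D = dissimilarity_matrix(X, "euclidean")
        Dp = dissimilarity_matrix(X[perm], "euclidean")
        lab = cut_to_k(agglomerate(D, "average"), 3).labels
        lab_p = cut_to_k(agglomerate(Dp, "average"), 3).labels
        # same partition up to label renaming
        for i in range(8):
            for j in range(8):
                assert (lab[perm[i]] == lab[perm[j]]) == (lab_p[i] == lab_p[j])

    def test_unknown_linkage_rejected(self):
        with pytest.raises(InvalidParameterError):
            agglomerate(three_object_distances(), "ward2")


class TestCuts:
    def test_cut_heights_bracket_singletons_and_one_cluster(self):
        dend = agglomerate(three_object_distances(), "mcquitty")
        assert cut_at_height(dend, 0.5).k == 3
        assert cut_at_height(dend, 100.0).k == 1
        assert cut_at_height(dend, 2.0).k == 2

    def test_cut_to_k_matches_example(self):
        dend = agglomerate(three_object_distances(), "mcquitty")
        two = cut_to_k(dend, 2)
        assert two.labels.tolist() == [1, 1, 2]  # {A,B}, {C}
        assert cut_to_k(dend, 1).k == 1
        assert cut_to_k(dend, 3).k == 3

    def test_cut_equivalence_between_height_and_k(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 5))
        dend = agglomerate(dissimilarity_matrix(X, "euclidean"), "average")
        hs = np.sort(dend.heights)
        for k in (2, 4, 7):
            h = (hs[10 - k - 1] + hs[10 - k]) / 2
            np.testing.assert_array_equal(
                cut_to_k(dend, k).labels, cut_at_height(dend, h).labels
            )

    def test_k_out_of_range(self):
        dend = agglomerate(three_object_distances(), "single")
        with pytest.raises(InvalidParameterError):
            cut_to_k(dend, 0)


class TestContingency:
    def test_counting_example(self):
        asg = ClusterAssignment(np.array([1, 1, 2]), 2, "k")
        tab = cluster_contingency(asg, np.array(["AVR", "AVR", "Ross"]))
        np.testing.assert_array_equal(tab.counts, [[2, 0], [0, 1]])

    def test_single_cluster_column_equals_group_tallies(self):
        groups = np.array(["AVR"] * 3 + ["Ross"] * 2)
        asg = ClusterAssignment(np.ones(5, dtype=int), 1, "k")
        tab = cluster_contingency(asg, groups)
        np.testing.assert_array_equal(tab.counts, [[3], [2]])

    def test_cell_sum_is_n(self):
        rng = np.random.default_rng(11)
        groups = rng.choice(["AVR", "Ozaki", "Ross", "VS"], size=30)
        labels = rng.integers(1, 5, size=30)
        labels[:4] = [1, 2, 3, 4]  # all clusters present
        asg = ClusterAssignment(labels, 4, "k")
        assert cluster_contingency(asg, groups).counts.sum() == 30


class TestMajorityFraction:
    def test_twelve_of_thirteen(self):
        labels = np.array([2] * 12 + [4] + [1] * 10)
        groups = np.array(["Ross"] * 13 + ["AVR"] * 10)
        asg = ClusterAssignment(labels, 4, "k")
        assert majority_cluster_fraction(asg, groups, "Ross") == pytest.approx(12 / 13)

    def test_whole_group_one_cluster_and_even_spread(self):
        groups = np.array(["Ross"] * 8)
        assert majority_cluster_fraction(
            ClusterAssignment(np.ones(8, dtype=int), 1, "k"), groups, "Ross"
        ) == 1.0
        assert majority_cluster_fraction(
            ClusterAssignment(np.array([1, 2, 3, 4] * 2), 4, "k"), groups, "Ross"
        ) == pytest.approx(1 / 4)

    def test_unknown_group_rejected(self):
        asg = ClusterAssignment(np.array([1, 1]), 1, "k")
        with pytest.raises(InvalidParameterError):
            majority_cluster_fraction(asg, np.array(["AVR", "AVR"]), "Ross")


def test_newick_export_parses_with_dendropy():
    import dendropy

    dend = agglomerate(three_object_distances(), "mcquitty",
                       leaf_labels=["A", "B", "C"])
    tree = dendropy.Tree.get(data=to_newick(dend), schema="newick")
    assert sorted(t.taxon.label for t in tree.leaf_node_iter()) == ["A", "B", "C"]
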