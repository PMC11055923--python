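"""Variable-relationship structure: correlation, sign-independent clustering,
cophenetic validation, permutation reliability, and factor analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import pdist, squareform

from ratpheno.core_data import zscore
from ratpheno.feature_structure import (
    clustering_reliability,
    cophenetic_coefficient,
    cut_tree,
    factor_analysis,
    label_separation_test,
    sign_independent_distance,
    sign_independent_pdist,
    spearman_matrix,
    varimax,
    ward_linkage,
)
from ratpheno.synthetic import generate_battery, shuffle_dataset


class TestSpearman:
    def test_monotone_and_sign(self, rng):
        x = rng.normal(size=30)
        M = np.column_stack([x, np.exp(x), -x])
        res = spearman_matrix(M)
        assert res.r[0, 1] == pytest.approx(1.0)
        assert res.r[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(res.r), 1.0)
        np.testing.assert_allclose(res.r, res.r.T)

    def test_hand_rank_example(self):
        M = np.column_stack([[1, 2, 3, 4], [2, 1, 4, 3]])
        assert spearman_matrix(M).r[0, 1] == pytest.approx(0.6)


class TestSignIndependentDistance:
    def test_forced_identities(self):
        x = np.array([1.0, -2.0, 3.0])
        assert sign_independent_distance(x, -x) == 0.0
        assert sign_independent_distance(x, x) == 0.0
        assert sign_independent_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.sqrt(2))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sign_independent_distance([1.0], [1.0, 2.0])

    @given(
        arrays(float, 6, elements=st.floats(-50, 50)),
        arrays(float, 6, elements=st.floats(-50, 50)),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_by_euclidean_and_tight_when_aligned(self, x, y):
        d = sign_independent_distance(x, y)
        eu = float(np.linalg.norm(x - y))
        assert d <= eu + 1e-9
        if np.dot(x, y) >= 0:
            assert d == pytest.approx(eu, abs=1e-9)

    def test_pdist_matches_pairwise_definition(self, rng):
        X = rng.normal(size=(8, 5))
        D = squareform(sign_independent_pdist(X))
        for i in range(8):
            for j in range(8):
                assert D[i, j] == pytest.approx(
                    sign_independent_distance(X[i], X[j]), abs=1e-9
                )


def lance_williams_ward_oracle(D):
    """Brute-force Ward agglomeration via the Lance–Williams update on a
    squared-distance matrix; returns the merge heights in order."""
    D = D.astype(float).copy()
    sizes = {i: 1 for i in range(D.shape[0])}
    active = set(sizes)
    heights = []
    d2 = {frozenset((i, j)): D[i, j] ** 2 for i in active for j in active if i < j}
    next_id = D.shape[0]
    while len(active) > 1:
        pair = min(d2, key=lambda k: (d2[k], sorted(k)))
        i, j = sorted(pair)
        heights.append(np.sqrt(d2[pair]))
        ni, nj = sizes[i], sizes[j]
        active -= {i, j}
        for k in active:
            nk = sizes[k]
            dik = d2[frozenset((i, k))]
            djk = d2[frozenset((j, k))]
            dij = d2[pair]
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
            d2[frozenset((next_id, k))] = new
        d2 = {k: v for k, v in d2.items() if i not in k and j not in k}
        sizes[next_id] = ni + nj
        active.add(next_id)
        next_id += 1
    return np.array(heights)


class TestWardLinkage:
    def test_three_point_line_against_oracle(self):
        X = np.array([[0.0], [1.0], [10.0]])
        tree = ward_linkage(X, metric="euclidean")
        # first merge {0,1} at height 1
        assert set(tree.merges[0, :2].astype(int)) == {0, 1}
        oracle = lance_williams_ward_oracle(squareform(pdist(X)))
        np.testing.assert_allclose(tree.heights, oracle, atol=1e-10)
        assert tree.heights[1] > tree.heights[0]

    def test_random_points_against_oracle(self, rng):
        X = rng.normal(size=(7, 3))
        tree = ward_linkage(X, metric="euclidean")
        oracle = lance_williams_ward_oracle(squareform(pdist(X)))
        np.testing.assert_allclose(np.sort(tree.heights), np.sort(oracle), atol=1e-8)

    def test_identical_points_merge_at_zero(self):
        tree = ward_linkage(np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]]))
        assert tree.heights[0] == 0.0

    def test_anticorrelated_variables_merge_first(self, rng):
        x = rng.normal(size=20)
        items = np.vstack([x, -x, rng.normal(size=20)])
        tree = ward_linkage(items, metric="sign_independent")
        assert set(tree.merges[0, :2].astype(int)) == {0, 1}
        assert tree.heights[0] == pytest.approx(0.0, abs=1e-10)

    def test_heights_monotone_on_default_battery(self, default_z):
        tree = ward_linkage(default_z.values.T, metric="sign_independent")
        assert np.all(np.diff(tree.heights) >= -1e-10)

    def test_newick_export_covers_all_leaves(self):
        tree = ward_linkage(np.array([[0.0], [1.0], [10.0]]))
        nwk = tree.to_newick()
        assert nwk.endswith(";") and all(f"item{i}" in nwk for i in range(3))


class TestCophenetic:
    def test_ultrametric_input_reproduced(self):
        # distances already ultrametric: d(0,1)=1, d(0,2)=d(1,2)=4
        d = np.array([1.0, 4.0, 4.0])
        tree = ward_linkage(d, metric="precomputed")
        # correlation between cophenetic and original distances is exactly 1
        assert cophenetic_coefficient(tree, d) == pytest.approx(1.0)

    def test_three_point_hand_value(self):
        """d = (1,5,6): Ward merges {0,1} at 1, then at sqrt(121/3); the
        cophenetic vector is (1,h,h) and the correlation is computable by hand."""
        d = np.array([1.0, 5.0, 6.0])
        tree = ward_linkage(d, metric="precomputed")
        h = np.sqrt((2 * 25 + 2 * 36 - 1) / 3)
        coph = np.array([1.0, h, h])
        expected = np.corrcoef(coph, d)[0, 1]
        assert cophenetic_coefficient(tree, d) == pytest.approx(expected, abs=1e-10)

    def test_bounded_by_one(self, default_z):
        tree = ward_linkage(default_z.values.T, metric="sign_independent")
        c = cophenetic_coefficient(tree, sign_independent_pdist(default_z.values.T))
        assert -1.0 <= c <= 1.0


class TestCutTree:
    def test_extreme_cuts(self, rng):
        X = rng.normal(size=(6, 2))
        tree = ward_linkage(X)
        assert cut_tree(tree, 1).k == 1
        assert cut_tree(tree, 6).k == 6
        with pytest.raises(ValueError):
            cut_tree(tree, 7)

    def test_two_blob_split(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        cut = cut_tree(ward_linkage(X), 2)
        assert cut.labels[0] == cut.labels[1]
        assert cut.labels[2] == cut.labels[3]
        assert cut.labels[0] != cut.labels[2]

    def test_cuts_are_nested(self, default_z):
        tree = ward_linkage(default_z.values, metric="euclidean")
        for k in range(3, 8):
            coarse = cut_tree(tree, k - 1).labels
            fine = cut_tree(tree, k).labels
            # every fine cluster maps into exactly one coarse cluster
            for c in np.unique(fine):
                assert len(np.unique(coarse[fine == c])) == 1


class TestLabelSeparation:
    def test_perfect_and_null_tables(self):
        from ratpheno.feature_structure import ClusterAssignment

        a = ClusterAssignment(labels=np.repeat([0, 1], 10), k=2, method="manual")
        labels = np.repeat(["sus", "res"], 10)
        res = label_separation_test(a, labels)
        assert res.chi2 == pytest.approx(20.0)
        assert res.p < 0.001
        balanced = np.tile(["sus", "res"], 10)
        assert label_separation_test(a, balanced).chi2 == 0.0


class TestClusteringReliability:
    def test_fraction_one_gives_identical_p_values(self, default_battery, default_z):
        ds, _ = default_battery
        summary = clustering_reliability(
            default_z, ds.valences, fraction=1.0, n_iter=5, seed=0
        )
        assert np.unique(summary.p_values).size == 1

    def test_planted_vs_shuffled_regime(self, default_battery, default_z):
        ds, _ = default_battery
        planted = clustering_reliability(default_z, ds.valences, n_iter=100, seed=1)
        null = clustering_reliability(
            default_z, ds.valences, n_iter=100, seed=2, shuffled=True
        )
        assert planted.fraction_significant >= 0.5
        assert null.fraction_significant <= 0.10

    def test_variables_axis_runs(self, default_battery, default_z):
        ds, _ = default_battery
        s = clustering_reliability(
            default_z, ds.valences, axis="variables", n_iter=20, seed=3
        )
        assert 0.0 <= s.fraction_significant <= 1.0


class TestFactorAnalysis:
    @staticmethod
    def two_factor_data(rng, n=400):
        f = rng.standard_normal((n, 2))
        L = np.zeros((8, 2))
        L[:4, 0] = [0.9, 0.85, 0.8, 0.75]
        L[4:, 1] = [0.9, 0.85, 0.8, 0.75]
        return f @ L.T + 0.4 * rng.standard_normal((n, 8)), L

    def test_recovers_disjoint_block_structure(self, rng):
        X, L = self.two_factor_data(rng)
        sol = factor_analysis(zscore(X), n_factors=2)
        dominant = np.argmax(np.abs(sol.loadings), axis=1)
        assert len(set(dominant[:4])) == 1
        assert len(set(dominant[4:])) == 1
        assert dominant[0] != dominant[4]
        assert np.abs(sol.loadings[np.arange(8), dominant]).min() > 0.5

    def test_varimax_preserves_communalities(self, rng):
        X, _ = self.two_factor_data(rng)
        unrot = factor_analysis(zscore(X), n_factors=2, rotation=None)
        rot = factor_analysis(zscore(X), n_factors=2, rotation="varimax")
        np.testing.assert_allclose(
            np.sort(unrot.communalities), np.sort(rot.communalities), atol=1e-6
        )
        np.testing.assert_allclose(rot.communalities + rot.uniquenesses, 1.0, atol=1e-12)

    def test_reproduces_reduced_correlation_matrix(self, rng):
        X, _ = self.two_factor_data(rng, n=2000)
        Z = zscore(X)
        sol = factor_analysis(Z, n_factors=2)
        R = np.corrcoef(Z.values, rowvar=False)
        fitted = sol.loadings @ sol.loadings.T + np.diag(sol.uniquenesses)
        assert np.abs(R - fitted).max() < 0.05

    def test_varimax_is_orthogonal_rotation(self, rng):
        L = rng.normal(size=(10, 3))
        R = varimax(L)
        np.testing.assert_allclose(
            np.sort((L**2).sum(axis=1)), np.sort((R**2).sum(axis=1)), atol=1e-8
        )

    def test_battery_factors_dominated_by_single_tests(self, default_battery, default_z):
        """With one factor per test (minus one), most factors should load
        mainly on variables of a single test."""
        ds, _ = default_battery
        sol = factor_analysis(default_z, n_factors=7)
        tests = ds.tests
        single_test = 0
        for j in range(7):
            w = np.abs(sol.loadings[:, j])
            top = tests[np.argsort(w)[::-1][:2]]
            single_test += len(set(top)) == 1
        assert single_test >= 5

    def test_invalid_n_factors(self, default_z):
        with pytest.raises(ValueError):
            factor_analysis(default_z, n_factors=26)
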