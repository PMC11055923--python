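"""Individual-rat clustering: helplessness, k-means profiles, k selection,
profiles, and cross-algorithm correspondence."""

import numpy as np
import pytest

from ratpheno.core_data import DegenerateDataError, zscore
from ratpheno.feature_structure import ClusterAssignment
from ratpheno.individual_profiles import (
    classify_helplessness,
    cluster_correspondence,
    cluster_profiles,
    hier_profiles,
    hierarchy_scan,
    kmeans_best_of_restarts,
    select_k,
    silhouette_values,
)
from ratpheno.feature_structure import ward_linkage
from ratpheno.synthetic import generate_battery


def three_blobs(rng, n_per=20, sep=8.0):
    centers = np.array([[0.0, 0.0], [sep, 0.0], [0.0, sep]])
    X = np.vstack([c + rng.standard_normal((n_per, 2)) for c in centers])
    labels = np.repeat([0, 1, 2], n_per)
    return X, labels


class TestKMeans:
    def test_two_blob_recovery(self, rng):
        X = np.vstack(
            [rng.standard_normal((15, 2)), rng.standard_normal((15, 2)) + 10.0]
        )
        a = kmeans_best_of_restarts(X, 2, n_restarts=20, seed=0)
        assert len(np.unique(a.labels[:15])) == 1
        assert len(np.unique(a.labels[15:])) == 1
        assert a.labels[0] != a.labels[15]

    def test_k1_inertia_is_total_scatter(self, rng):
        X = rng.normal(size=(20, 3))
        a = kmeans_best_of_restarts(X, 1, n_restarts=5, seed=0)
        assert a.inertia == pytest.approx(((X - X.mean(0)) ** 2).sum(), rel=1e-9)

    def test_k_equals_n_zero_inertia(self, rng):
        X = rng.normal(size=(8, 2))
        a = kmeans_best_of_restarts(X, 8, n_restarts=5, seed=0)
        assert a.inertia == pytest.approx(0.0, abs=1e-12)

    def test_best_of_restarts_no_worse_than_single(self, rng):
        X, _ = three_blobs(rng)
        single = kmeans_best_of_restarts(X, 3, n_restarts=1, seed=7)
        many = kmeans_best_of_restarts(X, 3, n_restarts=100, seed=7)
        assert many.inertia <= single.inertia + 1e-9

    def test_deterministic_given_seed(self, rng):
        X, _ = three_blobs(rng)
        a = kmeans_best_of_restarts(X, 3, n_restarts=10, seed=5)
        b = kmeans_best_of_restarts(X, 3, n_restarts=10, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestSilhouette:
    def test_hand_example_squared_euclidean(self):
        """1-D clusters {0,1} vs {10,11}: point 0 has a=1, b=(100+121)/2,
        s = (110.5-1)/110.5 ≈ 0.9910."""
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        s, _ = silhouette_values(X, [0, 0, 1, 1])
        assert s[0] == pytest.approx((110.5 - 1) / 110.5, abs=1e-10)

    def test_identical_points_convention(self):
        X = np.zeros((4, 2))
        s, flags = silhouette_values(X, [0, 0, 1, 1])
        np.testing.assert_allclose(s, 0.0)
        assert flags

    def test_singleton_cluster_convention(self, rng):
        X = rng.normal(size=(5, 2))
        s, flags = silhouette_values(X, [0, 0, 0, 0, 1])
        assert s[4] == 1.0
        assert any("singleton" in f for f in flags)

    def test_well_separated_blobs_high_mean(self, rng):
        X, labels = three_blobs(rng)
        s, _ = silhouette_values(X, labels)
        assert s.mean() > 0.9

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            silhouette_values(rng.normal(size=(5, 2)), [0] * 5)


class TestClassifyHelplessness:
    def test_two_point_toy_higher_failures_is_H(self):
        from ratpheno.core_data import BehavioralDataset, VariableMeta

        meta = [
            VariableMeta("SB_escape_failures", "SB", "susceptibility"),
            VariableMeta("SB_mean_escape_latency", "SB", "susceptibility"),
        ]
        ds = BehavioralDataset(
            values=np.array([[0.0, 0.0], [10.0, 10.0]]),
            rat_ids=["a", "b"],
            group=["NS", "IS"],
            meta=meta,
        )
        hn, _ = classify_helplessness(ds, k_candidates=(2,), n_restarts=20, seed=0)
        assert list(hn) == ["NH", "H"]

    def test_affine_rescaling_invariance(self, default_battery):
        ds, _ = default_battery
        hn_a, _ = classify_helplessness(ds, n_restarts=50, seed=1)
        ds_scaled = ds.subset(ds.variable_names)
        j = ds_scaled.variable_names.index("SB_escape_failures")
        ds_scaled.values[:, j] = ds_scaled.values[:, j] * 40.0 + 7.0
        hn_b, _ = classify_helplessness(ds_scaled, n_restarts=50, seed=1)
        assert list(hn_a) == list(hn_b)

    def test_recovers_planted_helplessness(self, default_battery):
        ds, truth = default_battery
        hn, assign = classify_helplessness(ds, n_restarts=100, seed=2)
        agreement = np.mean((hn == "H") == truth.helpless)
        assert agreement >= 0.85
        assert assign.k == 2

    def test_degenerate_identical_rats_rejected(self):
        from ratpheno.core_data import BehavioralDataset, VariableMeta

        meta = [
            VariableMeta("SB_escape_failures", "SB", "susceptibility"),
            VariableMeta("SB_mean_escape_latency", "SB", "susceptibility"),
        ]
        ds = BehavioralDataset(
            values=np.ones((5, 2)),
            rat_ids=[f"r{i}" for i in range(5)],
            group=["NS"] * 5,
            meta=meta,
        )
        with pytest.raises(DegenerateDataError):
            classify_helplessness(ds, n_restarts=5, seed=0)

    def test_missing_variable_rejected(self, default_battery):
        ds, _ = default_battery
        with pytest.raises(ValueError, match="shuttle-box"):
            classify_helplessness(ds.subset(["OF_total_distance", "FST_immobility"]))


class TestSelectK:
    def test_silhouette_mode_finds_three_blobs(self, rng):
        X, _ = three_blobs(rng)
        sel = select_k(X, range(2, 8), mode="silhouette", n_restarts=20, seed=0)
        assert sel.k == 3

    def test_semi_supervised_returns_planted_k(self, rng):
        X, blobs = three_blobs(rng)
        # stress group tracks blob membership closely: blob 0 mostly NS
        groups = np.where(blobs == 0, "NS", "IS")
        flip = rng.random(len(groups)) < 0.1
        groups = np.where(flip, np.where(groups == "NS", "IS", "NS"), groups)
        sel = select_k(
            X, range(2, 6), mode="semi_supervised", groups=groups,
            n_restarts=20, seed=0,
        )
        assert sel.k == 3

    def test_semi_supervised_null_groups_no_selection(self, rng):
        X, _ = three_blobs(rng)
        sel_list = []
        for s in range(5):
            groups = np.random.default_rng(s).choice(["NS", "IS"], size=X.shape[0])
            sel = select_k(
                X, range(2, 6), mode="semi_supervised", groups=groups,
                n_restarts=20, seed=0,
            )
            sel_list.append(sel.k)
        assert sel_list.count(None) >= 3  # group-independent clusters rarely qualify

    def test_trivial_k_range(self, rng):
        X, _ = three_blobs(rng)
        sel = select_k(X, [2], mode="silhouette", n_restarts=10, seed=0)
        assert sel.k == 2

    def test_semi_supervised_requires_groups(self, rng):
        with pytest.raises(ValueError, match="group"):
            select_k(three_blobs(rng)[0], [2, 3], mode="semi_supervised")


class TestHierarchyAndProfiles:
    def test_hier_profiles_recovers_planted_split(self, rng):
        X = np.vstack(
            [rng.standard_normal((12, 4)), rng.standard_normal((12, 4)) + 6.0]
        )
        a = hier_profiles(X, 2)
        assert len(np.unique(a.labels[:12])) == 1
        assert len(np.unique(a.labels[12:])) == 1

    def test_hierarchy_scan_planted_groups_significant(self, default_battery, default_z):
        ds, _ = default_battery
        tree = ward_linkage(default_z.values, metric="euclidean")
        scan = hierarchy_scan(tree, ds.group, k_range=range(2, 8))
        assert len(scan) == 6
        assert (scan["p"] < 0.2).any()  # group structure visible at some cut

    def test_hierarchy_scan_flags_degenerate_cut(self, rng):
        X = rng.normal(size=(10, 3))
        tree = ward_linkage(X, metric="euclidean")
        scan = hierarchy_scan(tree, ["NS"] * 5 + ["IS"] * 5, k_range=[2, 10])
        assert scan.loc[scan["k"] == 10, "degenerate"].item()

    def test_cluster_profiles_single_cluster_near_zero(self, default_z):
        a = ClusterAssignment(labels=np.zeros(default_z.n_rows, dtype=int), k=1, method="x")
        prof = cluster_profiles(default_z, a, ["NS"] * default_z.n_rows)
        np.testing.assert_allclose(prof.mean_z, 0.0, atol=1e-10)

    def test_singleton_cluster_sem_is_nan(self, rng):
        X = rng.normal(size=(5, 3))
        labels = np.array([0, 0, 0, 0, 1])
        a = ClusterAssignment(labels=labels, k=2, method="x")
        prof = cluster_profiles(X, a, ["NS", "NS", "IS", "IS", "IS"])
        assert np.isnan(prof.sem_z[1]).all()
        assert prof.sizes.tolist() == [4, 1]
        assert prof.composition.loc[1, "IS"] == 1

    def test_planted_susceptibility_cluster_profile(self, default_battery, default_z):
        """The generalized-susceptibility cluster shows positive mean Z on
        susceptibility variables and negative on resilience variables."""
        ds, truth = default_battery
        sus_cluster = truth.profile_cluster.max()
        a = ClusterAssignment(labels=truth.profile_cluster, k=3, method="truth")
        prof = cluster_profiles(default_z, a, ds.group)
        row = list(prof.cluster_ids).index(sus_cluster)
        sus_vars = ds.valences == "susceptibility"
        assert prof.mean_z[row, sus_vars].mean() > 0
        assert prof.mean_z[row, ~sus_vars].mean() < 0


class TestCorrespondence:
    def test_identical_and_relabeled(self, rng):
        labels = rng.integers(0, 3, size=30)
        a = ClusterAssignment(labels=labels, k=3, method="a")
        b = ClusterAssignment(labels=(labels + 1) % 3, k=3, method="b")
        assert cluster_correspondence(a, a).agreement == 1.0
        assert cluster_correspondence(a, b).agreement == 1.0

    def test_independent_assignments_near_chance(self):
        rng = np.random.default_rng(0)
        agreements = []
        for _ in range(20):
            a = ClusterAssignment(labels=rng.integers(0, 6, size=45), k=6, method="a")
            b = ClusterAssignment(labels=rng.integers(0, 6, size=45), k=6, method="b")
            agreements.append(cluster_correspondence(a, b).agreement)
        # chance level ~1/k plus optimal-matching inflation; well below 0.6
        assert 1 / 6 <= np.mean(agreements) <= 0.5

    def test_item_mismatch_rejected(self):
        a = ClusterAssignment(labels=np.zeros(5, dtype=int), k=1, method="a")
        b = ClusterAssignment(labels=np.zeros(6, dtype=int), k=1, method="b")
        with pytest.raises(ValueError):
            cluster_correspondence(a, b)
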