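import numpy as np
import pytest

from qsmlm import (
    CentroidLinkageClusterer,
    DBSCANClusterer,
    centroid_linkage_cluster,
    dbscan,
    size_survival_curve,
    summarize_clusters,
)
from _oracles import (
    brute_force_centroid_linkage,
    brute_force_dbscan,
    canonical_partition,
    convex_hull_area_shoelace,
)
from conftest import make_table


class TestDBSCAN:
    def test_two_blobs_two_clusters_no_noise(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 20, (50, 2)),
                       rng.normal([1000, 0], 20, (50, 2))])
        labels = dbscan(make_table(X), eps=100, min_pts=5)
        assert set(labels) == {0, 1}
        np.testing.assert_array_equal(
            canonical_partition(labels), brute_force_dbscan(X, 100, 5))

    def test_isolated_point_is_noise(self):
        labels = dbscan(make_table([[0, 0]]), eps=50, min_pts=2)
        assert list(labels) == [-1]

    def test_sparse_line_all_noise(self):
        X = np.column_stack([np.arange(10) * 200.0, np.zeros(10)])
        labels = dbscan(make_table(X), eps=100, min_pts=2)
        assert (labels == -1).all()

    def test_empty_input(self):
        est = DBSCANClusterer(eps=10, min_pts=2).fit(np.empty((0, 2)))
        assert len(est.labels_) == 0

    def test_matches_bruteforce_on_random_scenes(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            n = int(rng.integers(5, 200))
            X = rng.uniform(0, 1000, size=(n, 2))
            eps = float(rng.uniform(30, 150))
            min_pts = int(rng.integers(2, 8))
            got = canonical_partition(
                DBSCANClusterer(eps=eps, min_pts=min_pts).fit(X).labels_)
            want = brute_force_dbscan(X, eps, min_pts)
            np.testing.assert_array_equal(got, want)

    def test_agrees_with_sklearn_on_core_points(self):
        """Independent library cross-check: core-point partitions must
        agree exactly (border assignment is convention-dependent)."""
        from sklearn.cluster import DBSCAN as SkDBSCAN

        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 30, (60, 2)),
                       rng.normal([600, 600], 30, (60, 2)),
                       rng.uniform(0, 800, (30, 2))])
        est = DBSCANClusterer(eps=80, min_pts=5).fit(X)
        sk = SkDBSCAN(eps=80, min_samples=5).fit(X)
        core = est.core_mask_
        np.testing.assert_array_equal(
            np.flatnonzero(core), sk.core_sample_indices_)
        np.testing.assert_array_equal(
            canonical_partition(est.labels_[core]),
            canonical_partition(sk.labels_[core]))

    def test_invariant_under_rotation_translation(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(0, 500, size=(120, 2))
        a = canonical_partition(DBSCANClusterer(60, 4).fit(X).labels_)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        Xr = X @ R.T + [1e4, -3e3]
        b = canonical_partition(DBSCANClusterer(60, 4).fit(Xr).labels_)
        np.testing.assert_array_equal(a, b)


class TestCentroidLinkage:
    def test_hand_executed_three_points(self):
        # 0 and 60 merge (gap 60 < 100); centroid 30 is 170 from 200 -> stop
        X = np.array([[0.0, 0], [60.0, 0], [200.0, 0]])
        est = CentroidLinkageClusterer(R=100, min_count=1).fit(X)
        assert [(i, j) for i, j, _ in est.merge_sequence_] == [(0, 1)]
        assert list(est.labels_) == [0, 0, 1]

    def test_all_far_apart_each_own_cluster(self):
        X = np.array([[0.0, 0], [500.0, 0], [0, 500.0]])
        labels = centroid_linkage_cluster(make_table(X), R=100, min_count=1)
        assert len(set(labels)) == 3

    def test_coincident_points_merge_first(self):
        X = np.array([[100.0, 0], [0.0, 0], [0.0, 0], [50.0, 0]])
        est = CentroidLinkageClusterer(R=200, min_count=1).fit(X)
        assert est.merge_sequence_[0][:2] == (1, 2)
        assert est.merge_sequence_[0][2] == 0.0

    def test_min_count_turns_small_clusters_into_noise(self):
        X = np.array([[0.0, 0], [10.0, 0], [1000.0, 0]])
        labels = centroid_linkage_cluster(make_table(X), R=50, min_count=2)
        assert list(labels) == [0, 0, -1]

    def test_merge_sequence_matches_bruteforce(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n = int(rng.integers(3, 60))
            X = rng.uniform(0, 500, size=(n, 2))
            R = float(rng.uniform(40, 200))
            est = CentroidLinkageClusterer(R=R, min_count=1).fit(X)
            seq, labels = brute_force_centroid_linkage(X, R)
            assert [(i, j) for i, j, _ in est.merge_sequence_] == \
                [(i, j) for i, j, _ in seq]
            np.testing.assert_allclose(
                [d for *_, d in est.merge_sequence_],
                [d for *_, d in seq], rtol=1e-12)
            np.testing.assert_array_equal(
                canonical_partition(est.labels_), labels)

    def test_invariant_under_rotation_translation(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 400, size=(50, 2))
        a = canonical_partition(CentroidLinkageClusterer(80, 1).fit(X).labels_)
        th = -1.1
        Rm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        b = canonical_partition(
            CentroidLinkageClusterer(80, 1).fit(X @ Rm.T + 500).labels_)
        np.testing.assert_array_equal(a, b)


class TestSummaries:
    def test_unit_square_area_and_centroid(self):
        t = make_table([[0, 0], [1, 0], [1, 1], [0, 1]])
        s = summarize_clusters(t, np.zeros(4, dtype=int))[0]
        assert s.area == pytest.approx(1.0)
        assert s.centroid == pytest.approx((0.5, 0.5))
        assert s.n_localizations == 4

    def test_two_point_cluster_zero_area(self):
        t = make_table([[0, 0], [5, 5]])
        s = summarize_clusters(t, np.zeros(2, dtype=int))[0]
        assert s.area == 0.0

    def test_hull_area_matches_shoelace_oracle(self):
        rng = np.random.default_rng(31)
        pts = rng.uniform(0, 300, size=(50, 2))
        t = make_table(pts)
        s = summarize_clusters(t, np.zeros(50, dtype=int))[0]
        assert s.area == pytest.approx(convex_hull_area_shoelace(pts), rel=1e-9)

    def test_counts_conservation_with_noise(self):
        rng = np.random.default_rng(6)
        t = make_table(rng.uniform(0, 100, size=(40, 2)))
        labels = np.array([0] * 15 + [1] * 20 + [-1] * 5)
        summ = summarize_clusters(t, labels)
        assert sum(s.n_localizations for s in summ) + 5 == 40


class TestSurvivalCurve:
    def test_counting(self):
        grid, surv = size_survival_curve(None, sizes=np.array([10, 20, 30]))
        assert surv[np.searchsorted(grid, 20)] == pytest.approx(2 / 3)
        assert surv[0] == 1.0

    def test_equal_sizes_step(self):
        grid, surv = size_survival_curve(None, sizes=np.array([7, 7, 7]))
        assert list(grid) == [7] and list(surv) == [1.0]

    def test_matches_ecdf_complement(self):
        rng = np.random.default_rng(12)
        sizes = rng.integers(5, 500, 200)
        grid, surv = size_survival_curve(None, sizes=sizes)
        ecdf_c = [(sizes >= s).sum() / len(sizes) for s in grid]
        np.testing.assert_allclose(surv, ecdf_c)
        assert (np.diff(surv) <= 0).all()

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            size_survival_curve([])
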