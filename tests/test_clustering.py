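"""K-means, knee selection, randomization null and SSD regression."""

import itertools

import numpy as np
import pytest

from nanosyn.annotations_io import SynapseReconstruction
from nanosyn.clustering import (
    ClusterResult,
    cluster_analysis,
    kmeans_lloyd,
    knee_point,
    randomize_within_psd,
    reconstruct_coordinates,
    regress_ssd_vs_size,
    ssd_curve,
)
from .conftest import make_profile


def brute_force_ssd(points: np.ndarray, k: int) -> float:
    """Exhaustive minimum SSD over all assignments of N points to k clusters."""
    best = np.inf
    for assign in itertools.product(range(k), repeat=len(points)):
        assign = np.asarray(assign)
        if len(set(assign.tolist())) < k:
            continue
        ssd = 0.0
        for j in range(k):
            grp = points[assign == j]
            ssd += float(np.sum((grp - grp.mean(axis=0)) ** 2))
        best = min(best, ssd)
    return best


class TestKMeans:
    def test_identical_points_zero_ssd(self):
        pts = np.ones((6, 2))
        _, _, ssd = kmeans_lloyd(pts, 3, seed=0)
        assert ssd == 0.0

    def test_unit_square_corners_k2(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        _, _, ssd = kmeans_lloyd(pts, 2, n_init=10, seed=1)
        # optimal: pair opposite edges, 4 x 0.5^2
        assert ssd == pytest.approx(1.0)

    def test_k_equals_n_singletons(self, rng):
        pts = rng.uniform(size=(5, 2))
        assign, cents, ssd = kmeans_lloyd(pts, 5, seed=2)
        assert ssd == pytest.approx(0.0, abs=1e-12)
        assert sorted(assign.tolist()) == [0, 1, 2, 3, 4]

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            kmeans_lloyd(np.zeros((3, 2)), 4)

    def test_oracle_equivalence_small_instances(self, rng):
        """Lloyd with restarts finds the exhaustive-partition optimum."""
        for trial in range(40):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, 4))
            pts = rng.uniform(0, 100, size=(n, 2))
            _, _, ssd = kmeans_lloyd(pts, k, n_init=30, seed=rng)
            assert ssd == pytest.approx(brute_force_ssd(pts, k), rel=1e-9, abs=1e-9)

    def test_matches_sklearn_on_well_separated_blobs(self, rng):
        sklearn = pytest.importorskip("sklearn.cluster")
        pts = np.concatenate([
            rng.normal((0, 0), 1.0, size=(20, 2)),
            rng.normal((50, 50), 1.0, size=(20, 2)),
        ])
        _, _, ssd = kmeans_lloyd(pts, 2, n_init=10, seed=3)
        sk = sklearn.KMeans(n_clusters=2, n_init=10, random_state=0).fit(pts)
        assert ssd == pytest.approx(sk.inertia_, rel=1e-6)


class TestSSDCurve:
    def test_single_point(self):
        assert ssd_curve(np.array([[1.0, 2.0]])).tolist() == [0.0]

    def test_monotone_non_increasing(self, rng):
        pts = rng.uniform(0, 100, size=(15, 2))
        curve = ssd_curve(pts, seed=4)
        assert np.all(np.diff(curve) <= 1e-9)
        assert curve[-1] == pytest.approx(0.0, abs=1e-9)

    def test_two_blobs_sharp_drop(self, rng):
        blobs = np.concatenate([
            rng.normal((0, 0), 1.0, size=(10, 2)),
            rng.normal((100, 0), 1.0, size=(10, 2)),
        ])
        curve = ssd_curve(blobs, seed=5)
        assert curve[0] > 100 * curve[1]
        uniform = rng.uniform(0, 100, size=(20, 2))
        ucurve = ssd_curve(uniform, seed=6)
        # relative first drop is much sharper for planted clusters
        assert 1 - curve[1] / curve[0] > 1 - ucurve[1] / ucurve[0]


class TestKneePoint:
    def test_sharp_knee_at_two(self):
        assert knee_point(np.array([100.0, 10.0, 8.0, 6.0, 5.0])) == 2

    def test_linear_curve_no_knee(self):
        assert knee_point(np.array([40.0, 30.0, 20.0, 10.0])) == 1

    def test_trivial_curves(self):
        assert knee_point(np.array([0.0])) == 1
        assert knee_point(np.array([5.0, 1.0])) == 1
        with pytest.raises(ValueError):
            knee_point(np.array([]))

    def test_shallow_curve_reports_one(self):
        # smooth 1/k decay has no pronounced knee
        k = np.arange(1, 16)
        assert knee_point(100.0 / k) == 1


def _synthetic_synapse(rng, centers, n_per, sigma=10.0, half=150.0, n_sections=7):
    """Reconstruction with gold planted around given (x, z-section) centers."""
    profs = [make_profile("syn", i, thickness=40.0, half=half) for i in range(n_sections)]
    syn = SynapseReconstruction("syn", profs)
    for cx, csec in centers:
        for _ in range(n_per):
            x = cx + rng.normal(0, sigma)
            sec = int(np.clip(round(csec + rng.normal(0, 0.5)), 0, n_sections - 1))
            syn.profile_at(sec).gold.append([x, 0.0])
    return syn


class TestClusterAnalysis:
    def test_planted_two_clusters_recovered(self, rng):
        hits = 0
        for trial in range(20):
            syn = _synthetic_synapse(rng, [(-80, 2), (80, 4)], n_per=8)
            res = cluster_analysis(syn, n_maps=3, seed=trial)
            hits += res.k_opt == 2
        assert hits >= 16  # >= 80% recovery

    def test_single_blob_one_cluster(self, rng):
        syn = _synthetic_synapse(rng, [(0, 3)], n_per=12, sigma=25.0)
        res = cluster_analysis(syn, n_maps=3, seed=9)
        assert res.k_opt == 1

    def test_data_ssd_below_null(self, rng):
        syn = _synthetic_synapse(rng, [(-80, 2), (80, 4)], n_per=8)
        res = cluster_analysis(syn, n_maps=20, seed=10)
        assert res.randomized_mean_ssd is not None
        assert res.ssd_at_kopt < res.randomized_mean_ssd

    def test_few_particles_skip_knee(self):
        profs = [make_profile("s", 0, gold=[(0, 0), (10, 0), (20, 0)])]
        res = cluster_analysis(SynapseReconstruction("s", profs), seed=1)
        assert res.k_opt == 1 and res.randomized_mean_ssd is None

    def test_empty_synapse(self):
        res = cluster_analysis(
            SynapseReconstruction("s", [make_profile("s", 0)]), seed=1
        )
        assert res.n_particles == 0 and res.k_opt == 0


class TestRandomizeWithinPSD:
    def _syn(self):
        # sections with very different trace lengths
        profs = [
            make_profile("s", 0, half=30.0),
            make_profile("s", 1, half=150.0),
            make_profile("s", 2, half=75.0),
        ]
        return SynapseReconstruction("s", profs)

    def test_count_preserved_and_deterministic(self):
        syn = self._syn()
        maps1 = randomize_within_psd(syn, 17, n_maps=5, seed=3)
        maps2 = randomize_within_psd(syn, 17, n_maps=5, seed=3)
        assert all(len(m) == 17 for m in maps1)
        assert all(np.array_equal(a, b) for a, b in zip(maps1, maps2))

    def test_counts_proportional_to_trace_length(self):
        from scipy import stats as sps

        syn = self._syn()
        pts = np.concatenate(randomize_within_psd(syn, 500, n_maps=20, seed=4))
        z = pts[:, 1]
        dz = {-40.0: 0, 0.0: 1, 40.0: 2}
        counts = np.array([np.sum(z == k) for k in sorted(dz)])
        expected = np.array([30.0, 150.0, 75.0])
        expected = expected / expected.sum() * counts.sum()
        assert sps.chisquare(counts, expected).pvalue > 0.01


class TestRegression:
    def _result(self, sid, ssd, null, area):
        return ClusterResult(sid, 10, 2, np.zeros((2, 2)), np.zeros(10, int),
                             np.array([ssd]), ssd, null, [5, 5], area)

    def test_exact_line(self):
        results = [self._result(f"s{i}", 2.0 * a, 1.0, a) for i, a in
                   enumerate([0.05, 0.1, 0.2, 0.4])]
        fit = regress_ssd_vs_size(results)
        assert fit["slope"] == pytest.approx(2.0)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_independent_noise_low_r2(self, rng):
        results = [
            self._result(f"s{i}", float(rng.normal(10, 1)), 1.0, float(a))
            for i, a in enumerate(rng.uniform(0.05, 0.5, size=100))
        ]
        assert regress_ssd_vs_size(results)["r_squared"] < 0.08

    def test_hand_computed_ols(self):
        xs = np.array([0.1, 0.2, 0.3])
        ys = np.array([1.0, 3.0, 4.0])
        results = [self._result(f"s{i}", y, 1.0, x) for i, (x, y) in
                   enumerate(zip(xs, ys))]
        fit = regress_ssd_vs_size(results)
        # normal equations by hand
        slope = np.sum((xs - xs.mean()) * (ys - ys.mean())) / np.sum((xs - xs.mean()) ** 2)
        assert fit["slope"] == pytest.approx(slope)
        assert fit["intercept"] == pytest.approx(ys.mean() - slope * xs.mean())

    def test_degenerate_predictor(self):
        results = [self._result(f"s{i}", 1.0, 1.0, 0.1) for i in range(5)]
        with pytest.raises(ValueError, match="degenerate"):
            regress_ssd_vs_size(results)


def test_reconstruct_coordinates_geometry():
    profs = [make_profile("s", i, thickness=20.0) for i in range(3)]
    profs[0].gold = [[-30.0, 0.0]]
    profs[2].gold = [[40.0, 0.0]]
    syn = SynapseReconstruction("s", profs)
    coords = reconstruct_coordinates(syn)
    assert coords.shape == (2, 2)
    assert coords[0].tolist() == [-30.0, -20.0]
    assert coords[1].tolist() == [40.0, 20.0]
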