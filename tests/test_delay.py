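import itertools

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

import eodloop as el
from eodloop.stats import TukeyPairs


def pair_from_times(ctrl, stim, fish_id="T", delay=10.0):
    dur = max(ctrl[-1], stim[-1]) + 1
    return el.SessionPair(
        fish_id=fish_id, delay_ms=delay,
        control=el.PulseTrain(np.asarray(ctrl, float), dur, "fish"),
        stim_fish=el.PulseTrain(np.asarray(stim, float), dur, "fish"),
        stimulus_log=el.PulseTrain(np.empty(0), dur, "stimulus"),
    )


class TestSummarizeExperiment:
    def test_identical_sessions(self, rng):
        t = np.cumsum(rng.uniform(50, 200, 300))
        s = el.summarize_experiment(pair_from_times(t, t))
        assert s.ks_D == 0.0
        assert s.pearson_r == pytest.approx(1.0)
        assert s.qq_area_norm == pytest.approx(1.0)

    def test_halved_ipis_halve_normalized_area(self, rng):
        ipis = rng.lognormal(np.log(140), 0.25, 2000)
        ctrl = np.cumsum(ipis)
        stim = np.cumsum(0.5 * ipis)
        s = el.summarize_experiment(pair_from_times(ctrl, stim))
        assert s.qq_area_norm == pytest.approx(0.5, abs=0.02)

    def test_null_simulation_area_near_one(self):
        p = el.FishParams(p_echo=0.0, scale_short=1.0, scale_long=1.0)
        proto = el.ProtocolConfig(delay_ms=60, control_min=5, stim_min=5, seed=30)
        s = el.summarize_experiment(el.simulate_closed_loop(p, proto))
        assert s.qq_area_norm == pytest.approx(1.0, abs=0.1)

    def test_unusable_session_raises(self):
        with pytest.raises(ValueError):
            el.summarize_experiment(pair_from_times([10.0], [10.0, 20.0]))


def wcss(points, labels):
    total = 0.0
    for lab in np.unique(labels):
        c = points[labels == lab]
        total += ((c - c.mean(axis=0)) ** 2).sum()
    return total


class TestKMeans:
    def test_well_separated(self):
        pts = np.array([[10, 1], [20, 1.2], [200, 10], [210, 9.5]])
        res = el.kmeans_2d(pts, seed=0)
        np.testing.assert_array_equal(res.labels, [0, 0, 1, 1])
        assert res.boundary_delay_ms == pytest.approx(110.0)

    def test_not_beaten_by_exhaustive_partitions(self, rng):
        pts = rng.uniform(0, 10, (10, 2))
        res = el.kmeans_2d(pts, seed=1, n_restarts=32)
        z = (pts - pts.mean(0)) / pts.std(0)
        best = min(
            wcss(z, np.isin(np.arange(10), list(subset)).astype(int))
            for k in range(1, 10)
            for subset in itertools.combinations(range(10), k)
        )
        assert wcss(z, res.labels) <= best + 1e-9

    def test_duplicated_points_same_partition(self):
        pts = np.array([[10, 1], [20, 1.2], [200, 10], [210, 9.5]])
        doubled = np.vstack([pts, pts])
        res = el.kmeans_2d(doubled, seed=0)
        np.testing.assert_array_equal(res.labels[:4], res.labels[4:])
        np.testing.assert_array_equal(res.labels[:4], [0, 0, 1, 1])

    def test_order_invariance(self, rng):
        pts = np.vstack([rng.normal([30, 2], 0.5, (6, 2)),
                         rng.normal([200, 9], 0.5, (6, 2))])
        perm = rng.permutation(12)
        a = el.kmeans_2d(pts, seed=0)
        b = el.kmeans_2d(pts[perm], seed=0)
        np.testing.assert_array_equal(a.labels[perm], b.labels)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            el.kmeans_2d(np.ones((5, 2)), seed=0)


class TestSilhouette:
    def test_two_tight_clusters_score_one(self):
        pts = np.array([[0.0], [0.0], [10.0], [10.0]])
        assert el.silhouette_mean(pts, np.array([0, 0, 1, 1])) == 1.0

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        pts = rng.normal(0, 1, (8, 2))
        labels = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        s_vals = []
        for i in range(8):
            a = np.mean([np.linalg.norm(pts[i] - pts[j])
                         for j in range(8) if labels[j] == labels[i] and j != i])
            b = np.mean([np.linalg.norm(pts[i] - pts[j])
                         for j in range(8) if labels[j] != labels[i]])
            s_vals.append((b - a) / max(a, b))
        expected = np.mean(s_vals)
        got = el.silhouette_mean(pts, labels)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(silhouette_score(pts, labels), abs=1e-12)

    def test_identical_points_score_zero(self):
        pts = np.zeros((6, 2))
        assert el.silhouette_mean(pts, np.array([0, 0, 0, 1, 1, 1])) == 0.0

    def test_singleton_cluster_scores_zero(self):
        pts = np.array([[0.0], [5.0], [5.1]])
        s = el.silhouette_mean(pts, np.array([0, 1, 1]))
        assert -1.0 <= s <= 1.0  # singleton contributes 0, not an error

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            el.silhouette_mean(np.zeros((4, 2)), np.zeros(4, int))


class TestClusterTukeyProfile:
    def test_identical_sessions_all_zero(self, rng):
        t = np.cumsum(rng.uniform(50, 200, 200))
        prof = el.cluster_tukey_profile([pair_from_times(t, t)])
        assert prof.overall_mean_diff_ms == 0.0
        ok = prof.n_pairs > 0
        np.testing.assert_allclose(prof.mean_diff_ms[ok], 0.0)

    def test_constant_shift_in_every_bin(self):
        x = np.linspace(40, 400, 120)
        tp = TukeyPairs(mean_ms=x - 10, diff_ms=np.full(120, -20.0))
        prof = el.cluster_tukey_profile([tp], bin_ms=3.0)
        ok = prof.n_pairs > 0
        np.testing.assert_allclose(prof.mean_diff_ms[ok], -20.0)
        assert prof.overall_mean_diff_ms == pytest.approx(-20.0)

    def test_bins_are_contiguous_3ms(self, rng):
        t = np.cumsum(rng.uniform(50, 200, 200))
        prof = el.cluster_tukey_profile([pair_from_times(t, t * 0.9)])
        np.testing.assert_allclose(np.diff(prof.bin_center_ms), 3.0)

    def test_effect_direction_recovery(self, default_params):
        """Short-delay (scale 0.5) batch shows a larger-magnitude, negative
        overall mean difference than a long-delay batch."""
        short, long_ = [], []
        for seed in range(4):
            ps = el.ProtocolConfig(delay_ms=30, control_min=2, stim_min=2, seed=seed)
            pl = el.ProtocolConfig(delay_ms=200, control_min=2, stim_min=2,
                                   seed=100 + seed)
            short.append(el.simulate_closed_loop(default_params, ps))
            long_.append(el.simulate_closed_loop(default_params, pl))
        pa = el.cluster_tukey_profile(short)
        pb = el.cluster_tukey_profile(long_)
        assert pa.overall_mean_diff_ms < 0
        assert abs(pa.overall_mean_diff_ms) > abs(pb.overall_mean_diff_ms)


class TestCriticalDelayReport:
    def test_midpoint_and_conventions(self):
        pts = np.array([[10, 1.0], [100, 1.2], [102, 10.0], [200, 9.5]])
        res = el.kmeans_2d(pts, seed=0)
        rep = el.critical_delay_report(res)
        assert rep["boundary_delay_ms"] == pytest.approx(101.0)
        assert rep["cluster_a_max_delay_ms"] == 100.0
        assert rep["cluster_b_min_delay_ms"] == 102.0

    def test_report_invariant_to_input_order(self, rng):
        pts = np.vstack([rng.normal([30, 2], 1, (5, 2)),
                         rng.normal([200, 9], 1, (5, 2))])
        rep1 = el.critical_delay_report(el.kmeans_2d(pts, seed=0))
        rep2 = el.critical_delay_report(el.kmeans_2d(pts[::-1], seed=0))
        for k in ("boundary_delay_ms", "cluster_a_size", "cluster_b_size",
                  "silhouette_mean"):
            assert rep1[k] == pytest.approx(rep2[k])
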