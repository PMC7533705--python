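"""Cluster permutation test, onset latencies, jackknife, correlations,
median split — each checked against an independent oracle where one exists."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gazebias.inference import (
    _jackknife_se,
    cluster_test,
    competition_correlations,
    jackknife_latency,
    median_split,
    median_split_towardness,
    onset_latency,
)

from test_metrics import epochs_from_x


def brute_force_cluster_p(data: np.ndarray, alpha: float = 0.05) -> dict:
    """Independent exhaustive sign-flip oracle for the one-sample cluster test.

    Enumerates all 2^n sign assignments with plain loops; returns observed
    clusters as {(start_idx, end_idx): p}.
    """
    n, n_t = data.shape
    thr = stats.t.ppf(1 - alpha / 2, df=n - 1)

    def tvals(x):
        m = x.mean(axis=0)
        s = x.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / (s / np.sqrt(n))
        t[s == 0] = 0.0
        return t

    def clusters(t):
        found = []
        i = 0
        while i < n_t:
            if abs(t[i]) > thr:
                sign = np.sign(t[i])
                j = i
                while j + 1 < n_t and np.sign(t[j + 1]) == sign and abs(t[j + 1]) > thr:
                    j += 1
                found.append((i, j, t[i : j + 1].sum()))
                i = j + 1
            else:
                i += 1
        return found

    obs = clusters(tvals(data))
    null_max = []
    for signs in itertools.product([-1.0, 1.0], repeat=n):
        flipped = data * np.array(signs)[:, None]
        cl = clusters(tvals(flipped))
        null_max.append(max((abs(m) for *_, m in cl), default=0.0))
    null_max = np.array(null_max)
    # exhaustive enumeration: the exact p is the tail fraction over all
    # 2^n sign assignments (the identity assignment ties by construction)
    return {
        (s, e): np.mean(null_max >= abs(m) - 1e-9 * (1 + abs(m)))
        for s, e, m in obs
    }


class TestClusterTest:
    def _signal_data(self, seed=0, n=5, n_t=60):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, n_t))
        x[:, 20:35] += 1.6  # embedded effect
        return x

    def test_all_zero_curves_give_no_clusters(self):
        res = cluster_test(np.zeros((6, 100)), np.arange(100.0), n_perm=100, seed=0)
        assert res.clusters == []

    def test_matches_exhaustive_enumeration_oracle(self):
        data = self._signal_data()
        oracle = brute_force_cluster_p(data)
        res = cluster_test(data, np.arange(60.0), n_perm=10_000, seed=42)
        assert len(res.clusters) == len(oracle)
        for c in res.clusters:
            p_exact = oracle[(int(c.start_ms), int(c.end_ms))]
            assert c.p == pytest.approx(p_exact, abs=0.02)

    def test_agrees_with_mne_cluster_statistics(self):
        mne_stats = pytest.importorskip("mne.stats")
        data = self._signal_data(seed=3, n=8, n_t=80)
        thr = stats.t.ppf(1 - 0.025, df=7)
        t_obs, clusters, _, _ = mne_stats.permutation_cluster_1samp_test(
            data, threshold=thr, tail=0, n_permutations=256, seed=1, out_type="mask"
        )
        mne_masses = sorted(float(t_obs[m].sum()) for m in clusters)
        res = cluster_test(data, np.arange(80.0), n_perm=1000, seed=1)
        ours = sorted(c.mass for c in res.clusters)
        np.testing.assert_allclose(ours, mne_masses, rtol=1e-10)

    def test_p_invariant_to_positive_scaling(self):
        data = self._signal_data(seed=1)
        r1 = cluster_test(data, np.arange(60.0), n_perm=500, seed=7)
        r2 = cluster_test(3.7 * data, np.arange(60.0), n_perm=500, seed=7)
        assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]

    def test_seeded_reproducibility(self):
        data = self._signal_data(seed=2)
        p1 = [c.p for c in cluster_test(data, np.arange(60.0), n_perm=500, seed=9).clusters]
        p2 = [c.p for c in cluster_test(data, np.arange(60.0), n_perm=500, seed=9).clusters]
        assert p1 == p2

    def test_paired_mode_equals_one_sample_on_differences(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(6, 50))
        b = rng.normal(size=(6, 50))
        r_paired = cluster_test(a, np.arange(50.0), data_b=b, n_perm=300, seed=3)
        r_diff = cluster_test(a - b, np.arange(50.0), n_perm=300, seed=3)
        assert [(c.start_ms, c.mass, c.p) for c in r_paired.clusters] == [
            (c.start_ms, c.mass, c.p) for c in r_diff.clusters
        ]

    def test_p_floor_is_one_over_nperm_plus_one(self):
        x = np.random.default_rng(8).normal(size=(12, 40)) + 5.0
        res = cluster_test(x, np.arange(40.0), n_perm=100, seed=0)
        assert min(c.p for c in res.clusters) >= 1 / 101

    def test_fewer_than_two_participants_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cluster_test(np.zeros((1, 10)), np.arange(10.0))

    def test_zero_variance_sample_treated_as_zero(self):
        x = np.random.default_rng(0).normal(size=(5, 20))
        x[:, 10] = 4.0  # identical across participants
        res = cluster_test(x, np.arange(20.0), n_perm=50, seed=0)
        assert all(not (c.start_ms <= 10 <= c.end_ms) or c.mass != np.inf
                   for c in res.clusters)


class TestOnsetLatency:
    def test_linear_ramp_crosses_10pct_at_450(self):
        t = np.arange(0.0, 2001.0)
        v = np.clip((t - 400) / 500, 0, 1) * 2.0  # 0→2% over 400–900 ms
        assert onset_latency(t, v) == pytest.approx(450.0, abs=1e-9)

    @pytest.mark.parametrize("c", [0.1, 1.0, 17.3])
    def test_scale_invariance(self, c):
        t = np.arange(0.0, 2001.0)
        v = np.clip((t - 300) / 400, 0, 1)
        assert onset_latency(t, c * v) == pytest.approx(onset_latency(t, v))

    def test_nonpositive_peak_is_undefined(self):
        t = np.arange(0.0, 100.0)
        assert np.isnan(onset_latency(t, -np.ones(100)))

    def test_interpolation_between_samples(self):
        t = np.arange(0.0, 5.0)
        v = np.array([0.0, 0.0, 1.0, 2.0, 2.0])
        # peak 2, threshold 0.2 crossed between t=1 (0.0) and t=2 (1.0)
        assert onset_latency(t, v, window_ms=(0, 4)) == pytest.approx(1.2)


class TestJackknife:
    def test_identical_participants_give_zero_se_and_zero_difference(self):
        t = np.arange(0.0, 1001.0)
        curve = np.clip((t - 200) / 300, 0, 1)
        a = np.tile(curve, (8, 1))
        est = jackknife_latency(a, a, t, window_ms=(0, 1000))
        assert est.se_diff_ms == 0.0
        assert est.t == 0.0 and est.p == 1.0

    def test_linear_statistic_se_matches_classical_sem(self):
        # jackknife SE of leave-one-out means equals the SEM algebraically
        rng = np.random.default_rng(10)
        vals = rng.normal(size=25)
        loo = np.array([np.delete(vals, i).mean() for i in range(len(vals))])
        assert _jackknife_se(loo) == pytest.approx(
            stats.sem(vals, ddof=1), abs=1e-10
        )

    def test_pure_time_shift_detected_as_degenerate(self):
        t = np.arange(0.0, 1001.0)
        a = np.tile(np.clip((t - 200) / 300, 0, 1), (6, 1))
        b = np.tile(np.clip((t - 400) / 300, 0, 1), (6, 1))
        est = jackknife_latency(a, b, t, window_ms=(0, 1000))
        assert est.degenerate
        assert est.difference_ms == pytest.approx(200.0)
        assert est.p == 0.0

    def test_reports_leave_one_out_failures(self):
        t = np.arange(0.0, 501.0)
        rng = np.random.default_rng(1)
        a = np.tile(np.clip((t - 100) / 100, 0, 1), (4, 1)) + 0.01 * rng.normal(
            size=(4, 501)
        )
        b = a.copy()
        b[0] = -50.0  # removing others leaves a negative-peak grand average
        est = jackknife_latency(a, b, t, window_ms=(0, 500))
        assert est.n_failed > 0
        assert est.flags


class TestCompetitionCorrelations:
    def _curves(self, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0.0, 2001.0)
        template = np.exp(-((t - 600) ** 2) / (2 * 200**2))
        null = template[None, :] * rng.uniform(0.5, 1.5, size=(10, 1))
        return t, null

    def test_perfect_match_gives_r_one(self):
        t, null = self._curves()
        pro = 2 * null
        anti = np.zeros_like(null)  # pro − anti = 2 × null exactly
        out = competition_correlations(null, pro, anti, t)
        assert out["r_time"] == pytest.approx(1.0)
        assert out["r_participants"] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        t, null = self._curves(1)
        out = competition_correlations(null, np.zeros_like(null), 2 * null, t)
        assert out["r_time"] == pytest.approx(-1.0)
        assert out["r_participants"] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        t = np.arange(0.0, 2001.0)
        flat = np.zeros((5, 2001))
        out = competition_correlations(flat, flat, flat, t)
        assert np.isnan(out["r_time"])
        assert "flags" in out


class TestMedianSplit:
    def test_strictly_below_rule(self):
        mask = median_split(np.array([1, 2, 3, 4, 5]))
        assert mask.tolist() == [True, True, False, False, False]

    def test_all_equal_gives_empty_good_half(self):
        assert not median_split(np.full(6, 2.0)).any()

    def test_towardness_split_flags_degenerate_participants(self):
        rng = np.random.default_rng(0)
        n_trials, n_t = 24, 100
        eps, sides, frames = {}, {}, []
        for p in (1, 2, 3):
            x = rng.normal(size=(n_trials, n_t))
            ep = epochs_from_x(x, participant=p)
            eps[p] = ep
            sides[p] = pd.Series(["left", "right"] * (n_trials // 2))
            err = rng.uniform(0, 40, n_trials) if p != 3 else np.full(n_trials, 5.0)
            frames.append(
                pd.DataFrame(
                    {
                        "participant": p,
                        "trial": ep.trial_ids,
                        "error_deg": err,
                    }
                )
            )
        out = median_split_towardness(
            pd.concat(frames, ignore_index=True),
            eps,
            sides,
            condition="pro",
            by="error",
            n_perm=100,
            seed=0,
        )
        # participant 3 has all-equal errors: empty good half, flagged missing
        assert out["missing_participants"] == [3]
        assert sorted(out["participants"]) == [1, 2]
        assert out["good"].shape == out["poor"].shape
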