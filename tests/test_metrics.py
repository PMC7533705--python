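"""Side coding, fixation filter, towardness, smoothing, and density maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazebias.containers import Epochs
from gazebias.metrics import (
    GOAL_CODED,
    MATCH_CODED,
    assign_side,
    density_difference,
    density_map,
    filter_fixation_trials,
    smooth_gaussian,
    towardness,
)

from conftest import trial_row, trials_frame


def epochs_from_x(x, time0=0.0, participant=1, invalid=()):
    x = np.atleast_2d(np.asarray(x, float))
    return Epochs(
        participant=participant,
        trial_ids=np.arange(1, x.shape[0] + 1),
        time_ms=np.arange(x.shape[1], dtype=float) + time0,
        x=x,
        y=np.zeros_like(x),
        valid=np.ones_like(x, bool),
        invalid_trials=set(invalid),
    )


class TestAssignSide:
    def test_null_match_coding(self):
        t = trials_frame([trial_row("match", "purple", "purple", "green", "left")])
        assert assign_side(t, MATCH_CODED).tolist() == ["left"]

    def test_anti_goal_coding_points_to_nonmatching_item(self):
        # anti cue purple, purple left / green right: green (right) is probed
        t = trials_frame([trial_row("anti", "purple", "purple", "green", "right")])
        assert assign_side(t, GOAL_CODED).tolist() == ["right"]

    def test_pro_goal_coding(self):
        t = trials_frame([trial_row("pro", "green", "purple", "green", "right")])
        assert assign_side(t, GOAL_CODED).tolist() == ["right"]

    def test_scheme_block_mismatch_raises(self):
        t = trials_frame([trial_row("match", "purple", "purple", "green", "left")])
        with pytest.raises(ValueError, match="does not apply"):
            assign_side(t, GOAL_CODED)
        t2 = trials_frame([trial_row("pro", "green", "green", "purple", "left")])
        with pytest.raises(ValueError, match="does not apply"):
            assign_side(t2, MATCH_CODED)

    def test_neutral_trials_rejected(self):
        t = trials_frame([trial_row("neutral", "gray", "purple", "green", "left")])
        with pytest.raises(ValueError, match="neutral"):
            assign_side(t, MATCH_CODED)


class TestFixationFilter:
    def test_peak_49_included_peak_51_excluded(self):
        x = np.zeros((2, 100))
        x[0, 50] = 49.0
        x[1, 50] = 51.0
        mask, retention = filter_fixation_trials(epochs_from_x(x), bound_pct=50.0)
        assert mask.tolist() == [True, False]
        assert retention == 0.5

    def test_vertical_channel_also_checked(self):
        ep = epochs_from_x(np.zeros((1, 100)))
        ep.y[0, 10] = 60.0
        mask, _ = filter_fixation_trials(ep)
        assert not mask[0]

    def test_retention_is_exact_complement_of_constructed_excursions(self):
        rng = np.random.default_rng(0)
        n = 40
        x = rng.normal(scale=3.0, size=(n, 200)).clip(-40, 40)
        bad = rng.choice(n, size=9, replace=False)
        x[bad, 100] = 80.0
        mask, retention = filter_fixation_trials(epochs_from_x(x))
        assert retention == (n - 9) / n
        assert set(np.flatnonzero(~mask)) == set(bad)

    def test_upstream_invalid_trials_excluded(self):
        mask, _ = filter_fixation_trials(epochs_from_x(np.zeros((2, 10)), invalid=(1,)))
        assert mask.tolist() == [False, True]

    def test_span_restricts_the_check(self):
        x = np.zeros((1, 100))
        x[0, 90] = 99.0
        mask, _ = filter_fixation_trials(epochs_from_x(x), span_ms=(0, 80))
        assert mask[0]


class TestTowardness:
    def test_formula(self):
        x = np.vstack([np.full(50, 2.0), np.full(50, -2.0)])
        tc = towardness(epochs_from_x(x), np.array(["right", "left"]), smoothing_sd_ms=0)
        np.testing.assert_allclose(tc.values, 2.0)
        assert tc.n_left == 1 and tc.n_right == 1

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 120))
        sides = np.array(["left", "right"] * 5)
        t1 = towardness(epochs_from_x(x), sides)
        t2 = towardness(epochs_from_x(x), np.where(sides == "left", "right", "left"))
        np.testing.assert_allclose(t1.values, -t2.values, atol=1e-12)

    def test_missing_side_returns_none(self):
        tc = towardness(epochs_from_x(np.zeros((2, 10))), np.array(["left", "left"]))
        assert tc is None

    def test_null_distribution_centered_on_zero(self):
        # identical distributions on both sides: mean towardness across many
        # simulated participants stays within ±3 SE of 0 (exchangeability)
        rng = np.random.default_rng(7)
        n_participants, n_t = 1000, 50
        means = np.empty(n_participants)
        sides = np.array(["left"] * 6 + ["right"] * 6)
        for i in range(n_participants):
            x = rng.normal(size=(12, n_t))
            means[i] = towardness(epochs_from_x(x), sides, smoothing_sd_ms=0).values.mean()
        se = means.std(ddof=1) / np.sqrt(n_participants)
        assert abs(means.mean()) < 3 * se


class TestSmoothing:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(smooth_gaussian(np.full(500, 3.3)), 3.3)

    def test_impulse_peak_matches_kernel_height(self):
        x = np.zeros(1001)
        x[500] = 1.0
        out = smooth_gaussian(x, sd_ms=25)
        assert out[500] == pytest.approx(1.0 / (np.sqrt(2 * np.pi) * 25), rel=1e-3)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)  # unit mass

    def test_linearity_smoothing_commutes_with_subtraction(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 300))
        lhs = smooth_gaussian(a) - smooth_gaussian(b)
        rhs = smooth_gaussian(a - b)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 60.0))
    def test_scaling_equivariance(self, seed, c):
        x = np.random.default_rng(seed).normal(size=100)
        np.testing.assert_allclose(
            smooth_gaussian(c * x), c * smooth_gaussian(x), atol=1e-9 * max(c, 1)
        )


class TestDensity:
    def test_point_mass_at_origin(self):
        ep = epochs_from_x(np.zeros((3, 500)))
        m = density_map(ep, window_ms=(0, 499), smooth_sd_pct=0.0)
        i = np.argmin(np.abs(m.x_centers))
        assert m.values[i, i] == 1.0
        assert m.values.sum() == 1.0

    def test_unsigned_map_sums_to_one_before_smoothing(self):
        rng = np.random.default_rng(4)
        ep = epochs_from_x(rng.normal(scale=10, size=(5, 700)))
        ep.y = rng.normal(scale=10, size=(5, 700))
        m = density_map(ep, window_ms=(0, 699), smooth_sd_pct=0.0)
        assert m.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_identical_sets_give_zero_difference(self):
        rng = np.random.default_rng(5)
        x = rng.normal(scale=10, size=(5, 700))
        m1 = density_map(epochs_from_x(x), window_ms=(0, 699))
        m2 = density_map(epochs_from_x(x.copy()), window_ms=(0, 699))
        diff = density_difference(m1, m2)
        np.testing.assert_allclose(diff.values, 0.0, atol=1e-15)
        assert diff.signed

    def test_difference_map_integrates_to_zero(self):
        rng = np.random.default_rng(6)
        m1 = density_map(
            epochs_from_x(rng.normal(2, 8, size=(5, 700))), window_ms=(0, 699),
            smooth_sd_pct=0.0,
        )
        m2 = density_map(
            epochs_from_x(rng.normal(-2, 8, size=(5, 700))), window_ms=(0, 699),
            smooth_sd_pct=0.0,
        )
        assert abs(density_difference(m1, m2).values.sum()) < 1e-10

    def test_out_of_range_samples_count_toward_total(self):
        x = np.zeros((1, 100))
        x[0, :50] = 500.0  # far outside the ±100 grid
        m = density_map(epochs_from_x(x), window_ms=(0, 99), smooth_sd_pct=0.0)
        assert m.values.sum() == pytest.approx(0.5)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError, match="empty"):
            density_map(epochs_from_x(np.zeros((1, 10))), window_ms=(400, 1000))


def test_plot_export_writes_figure(tmp_path):
    pytest.importorskip("matplotlib")
    from gazebias.metrics import ConditionCurves, plot_towardness

    rng = np.random.default_rng(0)
    cc = ConditionCurves(condition="pro", time_ms=np.arange(100.0))
    for p in range(3):
        tc = towardness(
            epochs_from_x(rng.normal(size=(6, 100)), participant=p),
            np.array(["left", "right"] * 3),
            "pro",
        )
        cc.add(tc)
    out = tmp_path / "towardness.png"
    plot_towardness({"pro": cc}, path=out)
    assert out.stat().st_size > 0
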