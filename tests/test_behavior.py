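"""Circular errors, RT trimming, the 2×2 decomposition, and the swap
mixture model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazebias.behavior import (
    circular_error,
    classify_correct,
    exclusion_flag,
    fit_report_mixture,
    remove_rt_outliers,
    two_by_two,
)


class TestCircularError:
    @pytest.mark.parametrize(
        "report,target,expected",
        [(175, 10, 15), (30, 30, 0), (0, 90, 90), (179, 0, 1), (100, 10, 90)],
    )
    def test_examples(self, report, target, expected):
        assert circular_error(report, target) == pytest.approx(expected)

    def test_matches_brute_force_on_all_integer_pairs(self):
        a, b = np.meshgrid(np.arange(180), np.arange(180), indexing="ij")
        ours = circular_error(a.ravel().astype(float), b.ravel().astype(float))
        # independent oracle: minimum over explicit ±180k shifts
        shifts = np.array([-360, -180, 0, 180, 360])[:, None]
        brute = np.abs(a.ravel() - b.ravel() + shifts).min(axis=0)
        np.testing.assert_array_equal(ours, brute)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(-720, 720, allow_nan=False),
        st.floats(-720, 720, allow_nan=False),
        st.integers(-3, 3),
    )
    def test_symmetry_and_period_invariance(self, a, b, k):
        assert circular_error(a, b) == pytest.approx(circular_error(b, a), abs=1e-9)
        assert circular_error(a + 180 * k, b) == pytest.approx(
            circular_error(a, b), abs=1e-9
        )
        assert 0 <= circular_error(a, b) <= 90


class TestRtOutliers:
    def test_all_equal_removes_none(self):
        assert remove_rt_outliers(np.full(20, 500.0)).all()

    def test_single_extreme_removed_first_iteration(self):
        rng = np.random.default_rng(0)
        rts = np.append(rng.normal(500, 20, 99), 10_000.0)
        mask = remove_rt_outliers(rts)
        assert not mask[-1]
        assert mask[:-1].all()
        # direct z computation on the constructed vector confirms it
        z = (rts - rts.mean()) / rts.std(ddof=1)
        assert abs(z[-1]) > 4

    def test_cascade_requires_second_pass(self):
        # a huge outlier inflates the SD enough to hide a moderate one;
        # manual iteration: pass 1 removes only the huge value, pass 2 the
        # moderate one
        base = np.concatenate([np.full(50, 500.0), [490.0, 510.0] * 25])
        rts = np.concatenate([base, [900.0, 100000.0]])
        z1 = (rts - rts.mean()) / rts.std(ddof=1)
        assert abs(z1[-1]) > 4 and abs(z1[-2]) < 4  # only the huge one at first
        kept1 = rts[np.abs(z1) <= 4]
        z2 = (kept1 - kept1.mean()) / kept1.std(ddof=1)
        assert abs(z2[-1]) > 4  # the moderate outlier unmasked
        mask = remove_rt_outliers(rts)
        assert not mask[-1] and not mask[-2]
        assert mask[:-2].all()

    def test_order_independent_and_idempotent(self):
        rng = np.random.default_rng(1)
        rts = np.append(rng.normal(600, 30, 80), [5000.0, 4000.0])
        mask = remove_rt_outliers(rts)
        perm = rng.permutation(len(rts))
        mask_perm = remove_rt_outliers(rts[perm])
        np.testing.assert_array_equal(mask_perm, mask[perm])
        np.testing.assert_array_equal(remove_rt_outliers(rts[mask]), True)


class TestTwoByTwo:
    def _means(self, rng, n=25, vol=2.0, inv=3.0, inter=0.0, noise=1.0):
        base = rng.normal(15, 2, size=n)
        eps = lambda: rng.normal(0, noise, size=n)  # noqa: E731
        return pd.DataFrame(
            {
                "pro": base - vol / 2 - inv / 2 + inter / 4 + eps(),
                "anti": base - vol / 2 + inv / 2 - inter / 4 + eps(),
                "match": base + vol / 2 - inv / 2 - inter / 4 + eps(),
                "nonmatch": base + vol / 2 + inv / 2 + inter / 4 + eps(),
            }
        )

    def test_no_effects_give_zero_interaction_contrast(self):
        rng = np.random.default_rng(0)
        v = rng.normal(10, 1, 12)
        w = rng.normal(12, 1, 12)
        df = pd.DataFrame({"pro": v, "anti": v, "match": w, "nonmatch": w})
        res = two_by_two(df)
        assert res.interaction.mean == pytest.approx(0.0, abs=1e-12)
        assert res.feature_match.mean == pytest.approx(0.0, abs=1e-12)

    def test_main_effect_equals_marginal_mean_difference(self):
        rng = np.random.default_rng(1)
        df = self._means(rng)
        res = two_by_two(df)
        marg = (df["match"] + df["nonmatch"]).mean() / 2 - (
            df["pro"] + df["anti"]
        ).mean() / 2
        assert res.informativeness.mean == pytest.approx(marg)

    def test_f_matches_repeated_measures_anova(self):
        pytest.importorskip("statsmodels")
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(2)
        df = self._means(rng, inter=1.5)
        res = two_by_two(df)
        long = df.reset_index(names="pid").melt(id_vars="pid", var_name="cond")
        long["informative"] = long["cond"].isin(["pro", "anti"]).astype(int)
        long["feature_match"] = long["cond"].isin(["pro", "match"]).astype(int)
        aov = AnovaRM(
            long, "value", "pid", within=["informative", "feature_match"]
        ).fit()
        tbl = aov.anova_table
        assert res.informativeness.F == pytest.approx(
            tbl.loc["informative", "F Value"], rel=1e-8
        )
        assert res.feature_match.F == pytest.approx(
            tbl.loc["feature_match", "F Value"], rel=1e-8
        )
        assert res.interaction.F == pytest.approx(
            tbl.loc["informative:feature_match", "F Value"], rel=1e-8
        )

    def test_missing_condition_drops_participant(self):
        rng = np.random.default_rng(3)
        df = self._means(rng, n=10)
        df.loc[0, "anti"] = np.nan
        res = two_by_two(df)
        assert len(res.condition_means) == 9

    def test_benefit_sign_convention(self):
        # lower scores (errors/RTs) after informative cues => positive benefit
        df = pd.DataFrame(
            {"pro": [10.0] * 5, "anti": [10.0] * 5, "match": [14.0] * 5,
             "nonmatch": [14.0] * 5}
        )
        res = two_by_two(df)
        assert (res.voluntary_benefit > 0).all()


def _mixture_sample(rng, n, w, kappa, n_items_apart=60.0):
    targets = rng.uniform(0, 180, n)
    nontargets = np.mod(targets + n_items_apart, 180)
    comp = rng.choice(3, size=n, p=w)
    err = np.degrees(rng.vonmises(0, kappa, n)) / 2
    reports = np.where(comp == 0, targets + err, np.where(comp == 1, nontargets + err, rng.uniform(0, 180, n)))
    return np.mod(reports, 180), targets, nontargets


class TestMixture:
    def test_reports_at_target_give_weight_one_and_capped_kappa(self):
        rng = np.random.default_rng(0)
        targets = rng.uniform(0, 180, 60)
        fit = fit_report_mixture(targets, targets, np.mod(targets + 60, 180))
        assert fit.w_target > 0.99
        assert fit.kappa == pytest.approx(500.0)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        reports, targets, nontargets = _mixture_sample(
            rng, 500, [0.85, 0.10, 0.05], kappa=12
        )
        fit = fit_report_mixture(reports, targets, nontargets, seed=2)
        assert fit.w_target == pytest.approx(0.85, abs=0.05)
        assert classify_correct(fit) == fit.w_target

    def test_uniform_reports_trigger_exclusion(self):
        rng = np.random.default_rng(2)
        targets = rng.uniform(0, 180, 200)
        reports = rng.uniform(0, 180, 200)
        fit = fit_report_mixture(reports, targets, np.mod(targets + 60, 180))
        assert fit.w_uniform > 0.5
        assert fit.w_target < 0.5
        assert exclusion_flag(fit)

    def test_loglik_non_decreasing_across_em_iterations(self):
        rng = np.random.default_rng(3)
        reports, targets, nontargets = _mixture_sample(
            rng, 200, [0.7, 0.2, 0.1], kappa=8
        )
        fit = fit_report_mixture(reports, targets, nontargets, restarts=1)
        trace = np.array(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-7).all()

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_report_mixture(np.zeros(10), np.zeros(10), np.full(10, 60.0))
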