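"""Behavioral pipeline: circular reproduction errors, RT outlier removal,
the 2×2 voluntary/involuntary decomposition, and the swap-mixture model used
for participant exclusion.

Reproduction errors live in the semicircular 180° feature space and range
0–90°. The 2×2 design crosses cue informativeness (pro/anti vs. match/
nonmatch) with cue-feature match (pro/match vs. anti/nonmatch); each
within-subject effect is tested as a one-sample t on its per-participant
contrast, with F = t², Cohen's d = mean/SD of the contrast, and partial
η² = t² / (t² + n − 1). Benefits are signed so that positive = better
performance (fewer degrees of error, fewer ms).

The mixture model doubles errors onto the 360° circle and fits, by EM, a
three-component mixture: a von Mises at the target, a same-concentration
von Mises at the non-target's (doubled) offset, and a uniform guess
component. The target weight is the fraction of correct-item reports;
participants with anti-block target weight < 0.5 are flagged for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

INFORMATIVE = ("pro", "anti")
UNINFORMATIVE = ("match", "nonmatch")
FEATURE_MATCH = ("pro", "match")
FEATURE_NONMATCH = ("anti", "nonmatch")
CONDITIONS = ("pro", "anti", "match", "nonmatch")


def circular_error(
    report: np.ndarray | float, target: np.ndarray | float, period: float = 180.0
) -> np.ndarray | float:
    """Minimal angular distance in a ``period``-periodic space, in [0, period/2].

    Symmetric in its arguments and invariant under adding multiples of the
    period to either one.
    """
    e = np.mod(np.abs(np.asarray(report, float) - np.asarray(target, float)), period)
    out = np.minimum(e, period - e)
    return float(out) if np.isscalar(report) and np.isscalar(target) else out


def remove_rt_outliers(
    rts: np.ndarray, z_bound: float = 4.0, max_iters: int = 3
) -> np.ndarray:
    """Iterative |z| > ``z_bound`` trimming; returns the inclusion mask.

    z-scores are recomputed against the currently included set; iteration
    stops when nothing is removed or after ``max_iters`` passes. With zero
    SD nothing is removed (z treated as 0). The mask depends only on the
    values, so it is order-independent and idempotent once converged.
    """
    rts = np.asarray(rts, float)
    if len(rts) < 2:
        return np.ones(len(rts), bool)
    mask = np.ones(len(rts), bool)
    for _ in range(max_iters):
        sub = rts[mask]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        z = np.zeros(len(rts))
        z[mask] = (sub - sub.mean()) / sd
        drop = mask & (np.abs(z) > z_bound)
        if not drop.any():
            break
        mask &= ~drop
    return mask


@dataclass
class EffectTest:
    """One within-subject contrast tested against zero."""

    name: str
    mean: float
    se: float
    t: float
    F: float
    df: tuple[int, int]
    p: float
    cohens_d: float
    partial_eta_sq: float

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mean": self.mean,
            "se": self.se,
            "t": self.t,
            "F": self.F,
            "df": list(self.df),
            "p": self.p,
            "cohens_d": self.cohens_d,
            "partial_eta_sq": self.partial_eta_sq,
        }


@dataclass
class BehavioralSummary:
    """2×2 decomposition of one performance measure (errors or RTs)."""

    measure: str
    condition_means: pd.DataFrame  # participant × condition
    voluntary_benefit: np.ndarray  # per participant, positive = benefit
    involuntary_benefit: np.ndarray
    informativeness: EffectTest
    feature_match: EffectTest
    interaction: EffectTest
    voluntary_vs_involuntary: EffectTest

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "voluntary_benefit_mean": float(self.voluntary_benefit.mean()),
            "involuntary_benefit_mean": float(self.involuntary_benefit.mean()),
            "informativeness": self.informativeness.to_dict(),
            "feature_match": self.feature_match.to_dict(),
            "interaction": self.interaction.to_dict(),
            "voluntary_vs_involuntary": self.voluntary_vs_involuntary.to_dict(),
        }


def _contrast_test(name: str, contrast: np.ndarray) -> EffectTest:
    c = np.asarray(contrast, float)
    n = len(c)
    sd = c.std(ddof=1)
    se = sd / np.sqrt(n)
    t = c.mean() / se if se > 0 else (0.0 if c.mean() == 0 else float("inf"))
    p = float(2 * stats.t.sf(abs(t), df=n - 1)) if np.isfinite(t) else 0.0
    t2 = t * t if np.isfinite(t) else float("inf")
    return EffectTest(
        name=name,
        mean=float(c.mean()),
        se=float(se),
        t=float(t),
        F=float(t2),
        df=(1, n - 1),
        p=p,
        cohens_d=float(c.mean() / sd) if sd > 0 else float("nan"),
        partial_eta_sq=float(t2 / (t2 + n - 1)) if np.isfinite(t2) else 1.0,
    )


def two_by_two(condition_means: pd.DataFrame, measure: str = "") -> BehavioralSummary:
    """Voluntary/involuntary decomposition from per-participant condition means.

    ``condition_means`` has one row per participant and columns pro, anti,
    match, nonmatch (participants with a missing condition are dropped).
    Voluntary benefit = mean(match, nonmatch) − mean(pro, anti); involuntary
    benefit = mean(anti, nonmatch) − mean(pro, match); both positive when the
    informative / feature-matching cues helped. The interaction contrast is
    (pro − anti) − (match − nonmatch). F from each contrast t equals the
    2×2 repeated-measures ANOVA F on the same data.
    """
    missing_cols = [c for c in CONDITIONS if c not in condition_means.columns]
    if missing_cols:
        raise ValueError(f"condition means missing columns: {missing_cols}")
    cm = condition_means[list(CONDITIONS)].dropna()
    if len(cm) < len(condition_means):
        dropped = set(condition_means.index) - set(cm.index)
        import logging

        logging.getLogger(__name__).info(
            "participants dropped for missing conditions: %s", sorted(dropped)
        )
    pro = cm["pro"].to_numpy()
    anti = cm["anti"].to_numpy()
    match = cm["match"].to_numpy()
    nonmatch = cm["nonmatch"].to_numpy()
    voluntary = (match + nonmatch) / 2 - (pro + anti) / 2
    involuntary = (anti + nonmatch) / 2 - (pro + match) / 2
    interaction = (pro - anti) - (match - nonmatch)
    return BehavioralSummary(
        measure=measure,
        condition_means=cm,
        voluntary_benefit=voluntary,
        involuntary_benefit=involuntary,
        informativeness=_contrast_test("cue informativeness", voluntary),
        feature_match=_contrast_test("cue feature match", involuntary),
        interaction=_contrast_test("interaction", interaction),
        voluntary_vs_involuntary=_contrast_test(
            "voluntary vs involuntary benefit", voluntary - involuntary
        ),
    )


# ---------------------------------------------------------------------------
# swap-mixture model on the doubled-angle circle


@dataclass
class MixtureFit:
    w_target: float
    w_nontarget: float
    w_uniform: float
    kappa: float
    log_likelihood: float
    converged: bool
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "w_target": self.w_target,
            "w_nontarget": self.w_nontarget,
            "w_uniform": self.w_uniform,
            "kappa": self.kappa,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def _a1(kappa: float) -> float:
    """Mean resultant length of a von Mises: A1(κ) = I1(κ)/I0(κ)."""
    return float(special.i1e(kappa) / special.i0e(kappa))


def _a1_inv(r: float, cap: float) -> float:
    if r <= 0:
        return 0.0
    if r >= _a1(cap):
        return cap
    return float(optimize.brentq(lambda k: _a1(k) - r, 1e-8, cap, xtol=1e-10))


def _vm_logpdf(x: np.ndarray, kappa: float) -> np.ndarray:
    # log of vM(x; 0, kappa); i0e avoids overflow at large kappa
    return kappa * np.cos(x) - kappa - np.log(2 * np.pi * special.i0e(kappa))


def _em(
    x: np.ndarray,
    delta: np.ndarray,
    w0: np.ndarray,
    kappa0: float,
    kappa_cap: float,
    tol: float,
    max_iter: int,
) -> MixtureFit:
    w = w0.copy()
    kappa = kappa0
    n = len(x)
    log_u = -np.log(2 * np.pi)
    prev = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = np.column_stack(
            [
                np.log(max(w[0], 1e-300)) + _vm_logpdf(x, kappa),
                np.log(max(w[1], 1e-300)) + _vm_logpdf(x - delta, kappa),
                np.full(n, np.log(max(w[2], 1e-300)) + log_u),
            ]
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        r = np.exp(logp - lse[:, None])
        w = r.mean(axis=0)
        denom = r[:, 0].sum() + r[:, 1].sum()
        if denom > 0:
            rbar = (r[:, 0] @ np.cos(x) + r[:, 1] @ np.cos(x - delta)) / denom
            kappa = _a1_inv(min(rbar, 1.0), kappa_cap)
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll
    return MixtureFit(
        w_target=float(w[0]),
        w_nontarget=float(w[1]),
        w_uniform=float(w[2]),
        kappa=float(kappa),
        log_likelihood=trace[-1],
        converged=converged,
        n_iter=it,
        loglik_trace=trace,
    )


def fit_report_mixture(
    reports: np.ndarray,
    targets: np.ndarray,
    nontargets: np.ndarray,
    kappa_cap: float = 500.0,
    restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = 0,
    min_trials: int = 30,
) -> MixtureFit:
    """Fit the 3-component swap mixture to continuous reports (180° space).

    Errors are doubled onto the 360° circle; the target and non-target
    components share one concentration κ (capped at ``kappa_cap`` for
    numerical stability on degenerate data). EM runs from ``restarts``
    jittered moment-based starts; the best log-likelihood is kept. If no
    start converges the best fit is still returned with ``converged=False``.
    """
    reports = np.asarray(reports, float)
    targets = np.asarray(targets, float)
    nontargets = np.asarray(nontargets, float)
    if not (len(reports) == len(targets) == len(nontargets)):
        raise ValueError("reports, targets, nontargets must align")
    if len(reports) < min_trials:
        raise ValueError(f"mixture fit needs at least {min_trials} trials")
    x = np.deg2rad(2.0 * (reports - targets))
    x = np.angle(np.exp(1j * x))
    delta = np.deg2rad(2.0 * (nontargets - targets))
    delta = np.angle(np.exp(1j * delta))
    # moment start: resultant of target-centered deviations
    rbar = float(np.abs(np.mean(np.exp(1j * x))))
    kappa0 = max(_a1_inv(rbar, kappa_cap), 1.0)
    rng = np.random.default_rng(seed)
    best: MixtureFit | None = None
    for i in range(restarts):
        if i == 0:
            w0 = np.array([0.8, 0.1, 0.1])
            k0 = kappa0
        else:
            w0 = rng.dirichlet([8.0, 1.0, 1.0])
            k0 = kappa0 * float(np.exp(0.5 * rng.standard_normal()))
        fit = _em(x, delta, w0, min(k0, kappa_cap), kappa_cap, tol, max_iter)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


def classify_correct(fit: MixtureFit) -> float:
    """Fraction of correct-item reports = mixture weight on the target."""
    return fit.w_target


def exclusion_flag(anti_fit: MixtureFit, threshold: float = 0.5) -> bool:
    """Participant exclusion rule: anti-block target weight below threshold."""
    return classify_correct(anti_fit) < threshold
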