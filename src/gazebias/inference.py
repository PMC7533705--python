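"""Inferential machinery for towardness time courses.

* Cluster-based permutation test: sample-wise one-sample t (on values or on
  paired differences), cluster-forming threshold at the two-tailed t critical
  value (α = 0.05, df n−1), clusters = maximal same-sign supra-threshold runs
  with mass = summed t, null distribution = max |cluster mass| over random
  sign flips of the participant curves, Monte-Carlo p = (1 + #null ≥ |mass|)
  / (n_perm + 1).
* Fractional-peak onset latency: first time the group curve reaches 10% of
  its in-window peak, with linear interpolation between the straddling 1-ms
  samples; undefined when the peak is not positive.
* Jackknife latency differences: leave-one-out latencies with the
  (n−1)/n-scaled SE that undoes the variance shrinkage of subsample
  statistics; t against zero with df n−1.
* Pearson competition correlations across time and across participants.
* Median-split linkage of gaze bias to trial-level behavior (strictly below
  the median = "good").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Epochs
from .metrics import TowardnessTimecourse, towardness

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    sign: int
    mass: float
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold: float
    n_permutations: int
    seed: int | None
    mode: str
    n_participants: int

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < 0.05]

    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_participants": self.n_participants,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "threshold": self.threshold,
            "clusters": [
                {
                    "start_ms": c.start_ms,
                    "end_ms": c.end_ms,
                    "sign": c.sign,
                    "mass": c.mass,
                    "p": c.p,
                }
                for c in self.clusters
            ],
        }


@dataclass
class LatencyEstimate:
    """Jackknife onset-latency estimate for a condition pair (and each side)."""

    condition_a: str
    condition_b: str
    onset_a_ms: float
    onset_b_ms: float
    se_a_ms: float
    se_b_ms: float
    difference_ms: float
    se_diff_ms: float
    t: float
    df: int
    p: float
    fraction: float
    n_failed: int = 0
    degenerate: bool = False
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "onset_a_ms": self.onset_a_ms,
            "onset_b_ms": self.onset_b_ms,
            "se_a_ms": self.se_a_ms,
            "se_b_ms": self.se_b_ms,
            "difference_ms": self.difference_ms,
            "se_diff_ms": self.se_diff_ms,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "fraction": self.fraction,
            "n_failed": self.n_failed,
            "degenerate": self.degenerate,
            "flags": self.flags,
        }


def _tvalues(x: np.ndarray) -> np.ndarray:
    """Sample-wise one-sample t across participants; zero-variance → t = 0."""
    n = x.shape[0]
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    zero = var <= 0
    if zero.any():
        logger.info("%d samples with zero variance; t set to 0", int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[zero] = 0.0
    return t


def _observed_clusters(
    t: np.ndarray, thr: float, time_ms: np.ndarray
) -> list[Cluster]:
    out: list[Cluster] = []
    for sign in (1, -1):
        mask = sign * t > thr
        if not mask.any():
            continue
        d = np.diff(mask.astype(np.int8), prepend=0, append=0)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1) - 1
        for s, e in zip(starts, ends):
            out.append(
                Cluster(
                    start_ms=float(time_ms[s]),
                    end_ms=float(time_ms[e]),
                    sign=sign,
                    mass=float(t[s : e + 1].sum()),
                    p=1.0,
                )
            )
    out.sort(key=lambda c: c.start_ms)
    return out


def _max_cluster_masses(T: np.ndarray, thr: float) -> np.ndarray:
    """Max |cluster mass| per row of a (n_perm, n_times) t-value matrix."""
    n_perm, n_t = T.shape
    out = np.zeros(n_perm)
    for sign in (1.0, -1.0):
        st = sign * T
        mask = st > thr
        if not mask.any():
            continue
        # pad a False column between rows so runs never span rows
        m2 = np.zeros((n_perm, n_t + 1), dtype=bool)
        m2[:, :n_t] = mask
        v2 = np.zeros((n_perm, n_t + 1))
        v2[:, :n_t] = np.where(mask, st, 0.0)
        flat = m2.ravel()
        d = np.diff(flat.astype(np.int8), prepend=np.int8(0))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        csum = np.concatenate([[0.0], np.cumsum(v2.ravel())])
        sums = csum[ends] - csum[starts]
        rows = starts // (n_t + 1)
        np.maximum.at(out, rows, sums)
    return out


def cluster_test(
    data: np.ndarray,
    time_ms: np.ndarray,
    data_b: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test on participant time courses.

    ``data`` is (n_participants, n_times); with ``data_b`` the test is paired
    (run on the per-participant differences ``data − data_b``), otherwise
    one-sample against 0. Requires n ≥ 2.
    """
    x = np.asarray(data, float)
    mode = "one-sample-vs-0"
    if data_b is not None:
        b = np.asarray(data_b, float)
        if b.shape != x.shape:
            raise ValueError("paired data sets must have matching shapes")
        x = x - b
        mode = "paired"
    n = x.shape[0]
    if n < 2:
        raise ValueError("cluster test requires at least 2 participants")
    if x.shape[1] != len(time_ms):
        raise ValueError("time axis does not match data")
    thr = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 1))
    t_obs = _tvalues(x)
    clusters = _observed_clusters(t_obs, thr, np.asarray(time_ms))
    if clusters:
        rng = np.random.default_rng(seed)
        sq = (x * x).sum(axis=0)
        null = np.empty(n_perm)
        block = 2000  # permutations per matmul block, bounds peak memory
        for lo in range(0, n_perm, block):
            k = min(block, n_perm - lo)
            signs = rng.choice([-1.0, 1.0], size=(k, n))
            m = signs @ x / n
            var = (sq - n * m * m) / (n - 1)
            np.clip(var, 0.0, None, out=var)
            with np.errstate(divide="ignore", invalid="ignore"):
                tp = m / np.sqrt(var / n)
            tp[~np.isfinite(tp)] = 0.0
            null[lo : lo + k] = _max_cluster_masses(tp, thr)
        for c in clusters:
            # tie tolerance: sign patterns that reproduce the observed mass
            # (e.g. the identity flip) must count as >= despite the slightly
            # different floating-point path of the vectorized null
            tol = 1e-9 * (1.0 + abs(c.mass))
            c.p = float((1 + np.sum(null >= abs(c.mass) - tol)) / (n_perm + 1))
    return ClusterResult(
        clusters=clusters,
        threshold=thr,
        n_permutations=n_perm,
        seed=seed,
        mode=mode,
        n_participants=n,
    )


def onset_latency(
    time_ms: np.ndarray,
    values: np.ndarray,
    fraction: float = 0.1,
    window_ms: tuple[float, float] = (0.0, 2000.0),
) -> float:
    """First time the curve reaches ``fraction`` × its in-window peak.

    Linear interpolation between the straddling samples removes grid
    quantization. Returns NaN (latency undefined) when the peak is ≤ 0.
    """
    t = np.asarray(time_ms, float)
    v = np.asarray(values, float)
    sel = (t >= window_ms[0]) & (t <= window_ms[1])
    tw, vw = t[sel], v[sel]
    if len(tw) == 0:
        raise ValueError("empty latency window")
    peak = vw.max()
    if peak <= 0:
        return float("nan")
    thr = fraction * peak
    above = vw >= thr
    i = int(np.argmax(above))
    if not above.any():
        return float("nan")
    if i == 0:
        return float(tw[0])
    t0, t1 = tw[i - 1], tw[i]
    v0, v1 = vw[i - 1], vw[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (thr - v0) / (v1 - v0) * (t1 - t0))


def _jackknife_se(values: np.ndarray) -> float:
    n = len(values)
    return float(np.sqrt((n - 1) / n * np.sum((values - values.mean()) ** 2)))


def jackknife_latency(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    time_ms: np.ndarray,
    fraction: float = 0.1,
    window_ms: tuple[float, float] = (0.0, 2000.0),
    condition_a: str = "a",
    condition_b: str = "b",
) -> LatencyEstimate:
    """Jackknife estimate of the onset-latency difference (b − a).

    Latencies are computed on grand-average curves; each participant is left
    out in turn and the SE is scaled by (n−1)/n. Leave-one-out latencies that
    are undefined are dropped and counted in ``n_failed``; a zero SE with a
    nonzero difference is flagged degenerate (p reported as 0).
    """
    a = np.asarray(curves_a, float)
    b = np.asarray(curves_b, float)
    if a.shape != b.shape:
        raise ValueError("condition curve sets must be paired (same shape)")
    n = a.shape[0]
    flags: list[str] = []

    def lat(x: np.ndarray) -> float:
        return onset_latency(time_ms, x.mean(axis=0), fraction, window_ms)

    full_a, full_b = lat(a), lat(b)
    diff = full_b - full_a
    loo_a = np.array([lat(np.delete(a, i, axis=0)) for i in range(n)])
    loo_b = np.array([lat(np.delete(b, i, axis=0)) for i in range(n)])
    loo_d = loo_b - loo_a
    bad = ~np.isfinite(loo_d)
    n_failed = int(bad.sum())
    if n_failed:
        flags.append(f"{n_failed} leave-one-out latencies undefined")
        loo_d = loo_d[~bad]
    se_a = _jackknife_se(loo_a[np.isfinite(loo_a)]) if np.isfinite(loo_a).sum() > 1 else float("nan")
    se_b = _jackknife_se(loo_b[np.isfinite(loo_b)]) if np.isfinite(loo_b).sum() > 1 else float("nan")
    degenerate = False
    if len(loo_d) < 2 or not np.isfinite(diff):
        t_stat, p, se_d = float("nan"), float("nan"), float("nan")
        flags.append("difference not estimable")
    else:
        se_d = _jackknife_se(loo_d)
        if se_d == 0.0:
            if diff == 0.0:
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = float("inf") * np.sign(diff), 0.0
                degenerate = True
                flags.append("zero jackknife SE with nonzero difference")
        else:
            t_stat = diff / se_d
            p = float(2 * stats.t.sf(abs(t_stat), df=n - 1))
    return LatencyEstimate(
        condition_a=condition_a,
        condition_b=condition_b,
        onset_a_ms=full_a,
        onset_b_ms=full_b,
        se_a_ms=se_a,
        se_b_ms=se_b,
        difference_ms=diff,
        se_diff_ms=se_d,
        t=float(t_stat),
        df=n - 1,
        p=p,
        fraction=fraction,
        n_failed=n_failed,
        degenerate=degenerate,
        flags=flags,
    )


def competition_correlations(
    null_curves: np.ndarray,
    pro_curves: np.ndarray,
    anti_curves: np.ndarray,
    time_ms: np.ndarray,
    time_window_ms: tuple[float, float] = (0.0, 2000.0),
    participant_window_ms: tuple[float, float] = (400.0, 800.0),
) -> dict:
    """Correlate 2 × null-block towardness with the pro − anti difference.

    The null-block match-vs-nonmatch gaze-bias difference is exactly double
    the match-coded towardness, so series A = 2 × null towardness and series
    B = pro − anti towardness. ``r_time``: Pearson across time points of the
    group means; ``r_participants``: Pearson across participants of the
    per-participant window means.
    """
    t = np.asarray(time_ms, float)
    a = 2.0 * np.asarray(null_curves, float)
    b = np.asarray(pro_curves, float) - np.asarray(anti_curves, float)
    sel_t = (t >= time_window_ms[0]) & (t <= time_window_ms[1])
    ga, gb = a.mean(axis=0)[sel_t], b.mean(axis=0)[sel_t]
    out: dict = {"n_participants": a.shape[0]}
    if np.std(ga) == 0 or np.std(gb) == 0:
        out["r_time"], out["p_time"] = float("nan"), float("nan")
        out["flags"] = ["zero variance across time"]
    else:
        r, p = stats.pearsonr(ga, gb)
        out["r_time"], out["p_time"] = float(r), float(p)
    sel_p = (t >= participant_window_ms[0]) & (t <= participant_window_ms[1])
    pa, pb = a[:, sel_p].mean(axis=1), b[:, sel_p].mean(axis=1)
    if np.std(pa) == 0 or np.std(pb) == 0:
        out["r_participants"], out["p_participants"] = float("nan"), float("nan")
        out.setdefault("flags", []).append("zero variance across participants")
    else:
        r, p = stats.pearsonr(pa, pb)
        out["r_participants"], out["p_participants"] = float(r), float(p)
        out["df_participants"] = a.shape[0] - 2
    return out


def median_split(values: np.ndarray) -> np.ndarray:
    """True = 'good' half: strictly below the median (deterministic tie rule)."""
    v = np.asarray(values, float)
    return v < np.median(v)


def median_split_towardness(
    trials: pd.DataFrame,
    epochs_by_participant: dict[int, Epochs],
    sides_by_participant: dict[int, pd.Series],
    condition: str,
    by: str = "error",
    measure_col: str | None = None,
    smoothing_sd_ms: float = 25.0,
    n_perm: int = 10_000,
    seed: int | None = 0,
    min_per_half_side: int = 2,
) -> dict:
    """Towardness for good vs. poor halves of a condition, plus a paired
    cluster test across participants.

    ``trials`` must be restricted to included trials of one condition and
    carry ``measure_col`` (default ``error_deg`` for ``by='error'``,
    ``rt_ms`` for ``by='rt'``). Splits are per participant, strictly below
    the participant's median = good. Participants with fewer than
    ``min_per_half_side`` trials per half per side are flagged missing.
    """
    if by not in ("error", "rt"):
        raise ValueError("by must be 'error' or 'rt'")
    measure_col = measure_col or ("error_deg" if by == "error" else "rt_ms")
    good_curves, poor_curves, participants, missing = [], [], [], []
    time_ms: np.ndarray | None = None
    for p, ep in sorted(epochs_by_participant.items()):
        tr = trials[trials["participant"] == p].set_index("trial")
        tr = tr.reindex(ep.trial_ids).dropna(subset=[measure_col])
        keep = np.isin(ep.trial_ids, tr.index.to_numpy())
        ep_p = ep.subset(keep)
        sides = np.asarray(sides_by_participant[p])[keep]
        vals = tr[measure_col].to_numpy()
        good = median_split(vals)
        ok = True
        for half in (good, ~good):
            for side in ("left", "right"):
                if np.sum(half & (sides == side)) < min_per_half_side:
                    ok = False
        if not ok:
            missing.append(p)
            continue
        tc_good = towardness(ep_p.subset(good), sides[good], condition, smoothing_sd_ms)
        tc_poor = towardness(ep_p.subset(~good), sides[~good], condition, smoothing_sd_ms)
        if tc_good is None or tc_poor is None:
            missing.append(p)
            continue
        good_curves.append(tc_good.values)
        poor_curves.append(tc_poor.values)
        participants.append(p)
        time_ms = tc_good.time_ms
    if len(participants) < 2:
        raise ValueError("median split needs at least 2 usable participants")
    g = np.vstack(good_curves)
    q = np.vstack(poor_curves)
    result = cluster_test(g, time_ms, data_b=q, n_perm=n_perm, seed=seed)
    return {
        "condition": condition,
        "by": by,
        "participants": participants,
        "missing_participants": missing,
        "time_ms": time_ms,
        "good": g,
        "poor": q,
        "cluster": result,
    }
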