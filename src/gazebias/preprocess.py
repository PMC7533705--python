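"""Raw binocular gaze → clean cyclopean, cue-locked epochs.

Stages: blink detection (pupil ≤ 0 in either eye, or gaze outside an optional
raw sanity bound), cubic-spline interpolation of ±``pad_ms`` around each blink,
left/right eye averaging, and epoching to retrocue onset on a shared time
axis. The sample grid is never altered — only values change. Trials whose
blinks abut a trial edge (no flanking data to anchor the spline) are flagged
invalid and excluded downstream rather than extrapolated.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .containers import (
    GAZE_CHANNELS,
    BinocularGaze,
    CyclopeanGaze,
    Epochs,
)

logger = logging.getLogger(__name__)

BlinkIntervals = dict[int, list[tuple[int, int]]]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as closed (start, end) index intervals."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _merge(intervals: list[tuple[int, int]], gap: float) -> list[tuple[int, int]]:
    if not intervals:
        return []
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = merged[-1]
        if s - pe < gap:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def detect_blinks(
    gaze: BinocularGaze,
    merge_gap_ms: float = 50.0,
    raw_bound: float | None = None,
) -> BlinkIntervals:
    """Blink intervals per trial, in ms from trial start (closed intervals).

    A sample is blink-like when either eye's pupil ≤ 0, or — with
    ``raw_bound`` set — any gaze channel leaves ``[-raw_bound, raw_bound]``.
    Intervals separated by less than ``merge_gap_ms`` are merged.
    """
    bad = (gaze.pupil_left <= 0) | (gaze.pupil_right <= 0)
    if raw_bound is not None:
        for c in GAZE_CHANNELS:
            bad |= np.abs(gaze.channel(c)) > raw_bound
    t0 = gaze.time_ms[0]
    out: BlinkIntervals = {}
    for i, tid in enumerate(gaze.trial_ids):
        ivs = _merge(_runs(bad[i]), merge_gap_ms)
        out[int(tid)] = [(int(s + t0), int(e + t0)) for s, e in ivs]
    return out


def interpolate_blinks(
    gaze: BinocularGaze,
    intervals: BlinkIntervals,
    pad_ms: float = 100.0,
    flank_ms: float = 200.0,
    anchor_bin_ms: float = 20.0,
) -> BinocularGaze:
    """Cubic-spline reconstruction of all four gaze channels around blinks.

    Each blink interval is padded by ``pad_ms`` on both sides; the spline is
    fit through up to ``flank_ms`` of clean samples per side (samples inside
    any padded interval are never used as anchors, which makes the operation
    idempotent). Flank samples are averaged into ``anchor_bin_ms`` bins before
    the fit — an interpolating cubic through every raw sample would inherit
    the measurement noise in its edge derivatives and swing wildly across the
    gap; bin means keep the reconstruction exact for constant and linear
    signals while bounding that amplification. A padded interval with fewer
    than 2 clean anchor samples on either side marks the trial invalid
    instead of interpolating.
    """
    out = gaze.copy()
    pad = int(pad_ms)
    flank = int(flank_ms)
    n_t = out.n_times
    t0 = out.time_ms[0]
    for i, tid in enumerate(out.trial_ids):
        ivs = intervals.get(int(tid), [])
        if not ivs:
            continue
        padded = _merge(
            [(int(s - t0) - pad, int(e - t0) + pad) for s, e in ivs], gap=1
        )
        in_padded = np.zeros(n_t, bool)
        for s, e in padded:
            in_padded[max(s, 0) : min(e, n_t - 1) + 1] = True
        ok = True
        for s, e in padded:
            if s < 0 or e > n_t - 1:
                ok = False
                break
            left = np.flatnonzero(~in_padded[max(s - flank, 0) : s])
            right = np.flatnonzero(~in_padded[e + 1 : min(e + 1 + flank, n_t)])
            if len(left) < 2 or len(right) < 2:
                ok = False
                break
        if not ok:
            out.invalid_trials.add(int(tid))
            logger.info(
                "trial %s: blink abuts trial edge or lacks flanking data; "
                "marked invalid",
                tid,
            )
            continue
        channels = [out.channel(c) for c in GAZE_CHANNELS]
        for s, e in padded:
            lo = max(s - flank, 0)
            hi = min(e + 1 + flank, n_t)
            anchor = np.flatnonzero(~in_padded[lo:hi]) + lo
            knot_t, starts, counts = _bin_anchors(anchor, anchor_bin_ms)
            fill = np.arange(s, e + 1, dtype=float)
            # (n_knots, 4): bin-mean of each gaze channel at the knots
            knot_v = np.column_stack(
                [
                    np.add.reduceat(ch[i, anchor], starts) / counts
                    for ch in channels
                ]
            )
            if len(knot_t) >= 4:
                recon = CubicSpline(knot_t, knot_v, axis=0)(fill)
            else:  # too few knots for a cubic: linear bridge per channel
                recon = np.column_stack(
                    [np.interp(fill, knot_t, knot_v[:, j]) for j in range(4)]
                )
            fi = fill.astype(int)
            for j, ch in enumerate(channels):
                ch[i, fi] = recon[:, j]
    return out


def _bin_anchors(
    anchor: np.ndarray, bin_ms: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group anchor indices into ~bin_ms bins of contiguous samples.

    Returns (knot times, reduceat start offsets into ``anchor``, bin sizes).
    """
    if bin_ms <= 1:
        n = len(anchor)
        return anchor.astype(float), np.arange(n), np.ones(n)
    bins = np.floor_divide(anchor, int(bin_ms))
    # split at bin changes or gaps in the anchor set
    cut = np.flatnonzero((np.diff(bins) != 0) | (np.diff(anchor) != 1)) + 1
    starts = np.concatenate([[0], cut])
    counts = np.diff(np.concatenate([starts, [len(anchor)]])).astype(float)
    knot_t = np.add.reduceat(anchor.astype(float), starts) / counts
    return knot_t, starts, counts


def average_eyes(gaze: BinocularGaze) -> CyclopeanGaze:
    """Cyclopean gaze: mean of the available eyes' positions per sample.

    An eye is unavailable at a sample when its channels are NaN; with exactly
    one eye available the other is used alone (monocular fallback). Samples
    with neither eye available are marked invalid.
    """
    xl, xr = gaze.x_left, gaze.x_right
    yl, yr = gaze.y_left, gaze.y_right
    if not (
        np.isnan(xl).any() or np.isnan(yl).any()
        or np.isnan(xr).any() or np.isnan(yr).any()
    ):
        return CyclopeanGaze(
            participant=gaze.participant,
            trial_ids=gaze.trial_ids.copy(),
            time_ms=gaze.time_ms.copy(),
            x=(xl + xr) / 2.0,
            y=(yl + yr) / 2.0,
            valid=np.ones(xl.shape, bool),
            invalid_trials=set(gaze.invalid_trials),
        )
    left_ok = ~(np.isnan(xl) | np.isnan(yl))
    right_ok = ~(np.isnan(xr) | np.isnan(yr))
    n_eyes = left_ok.astype(float) + right_ok.astype(float)
    with np.errstate(invalid="ignore"):
        x = (np.where(left_ok, xl, 0.0) + np.where(right_ok, xr, 0.0)) / np.where(
            n_eyes > 0, n_eyes, np.nan
        )
        y = (np.where(left_ok, yl, 0.0) + np.where(right_ok, yr, 0.0)) / np.where(
            n_eyes > 0, n_eyes, np.nan
        )
    return CyclopeanGaze(
        participant=gaze.participant,
        trial_ids=gaze.trial_ids.copy(),
        time_ms=gaze.time_ms.copy(),
        x=x,
        y=y,
        valid=n_eyes > 0,
        invalid_trials=set(gaze.invalid_trials),
    )


def epoch_to_cue(
    cyc: CyclopeanGaze,
    trials: pd.DataFrame,
    window_ms: tuple[float, float] = (-200.0, 2000.0),
) -> Epochs:
    """Re-index each trial to a shared axis of ms relative to retrocue onset.

    No baseline correction is applied — the left/right condition subtraction
    in towardness removes static offsets.
    """
    w0, w1 = int(window_ms[0]), int(window_ms[1])
    ep_time = np.arange(w0, w1 + 1, dtype=float)
    t0 = cyc.time_ms[0]
    cue = (
        trials.set_index("trial")["cue_onset_ms"]
        .reindex(cyc.trial_ids)
        .to_numpy()
    )
    if np.isnan(cue).any():
        missing = cyc.trial_ids[np.isnan(cue)]
        raise ValueError(f"trials missing cue onset: {missing.tolist()}")
    start = (cue + w0 - t0).astype(int)
    end = start + len(ep_time)
    if (start < 0).any() or (end > cyc.x.shape[1]).any():
        bad = cyc.trial_ids[(start < 0) | (end > cyc.x.shape[1])]
        raise ValueError(
            f"epoch window [{w0}, {w1}] ms exceeds recorded data for trials "
            f"{bad.tolist()}"
        )
    idx = start[:, None] + np.arange(len(ep_time))[None, :]
    rows = np.arange(cyc.x.shape[0])[:, None]
    return Epochs(
        participant=cyc.participant,
        trial_ids=cyc.trial_ids.copy(),
        time_ms=ep_time,
        x=cyc.x[rows, idx],
        y=cyc.y[rows, idx],
        valid=cyc.valid[rows, idx],
        invalid_trials=set(cyc.invalid_trials),
    )


def preprocess_participant(
    gaze: BinocularGaze,
    trials: pd.DataFrame,
    window_ms: tuple[float, float],
    merge_gap_ms: float = 50.0,
    pad_ms: float = 100.0,
    flank_ms: float = 200.0,
    anchor_bin_ms: float = 20.0,
    raw_bound: float | None = None,
) -> Epochs:
    """detect → interpolate → average → epoch, in the standard order."""
    intervals = detect_blinks(gaze, merge_gap_ms=merge_gap_ms, raw_bound=raw_bound)
    clean = interpolate_blinks(
        gaze, intervals, pad_ms=pad_ms, flank_ms=flank_ms, anchor_bin_ms=anchor_bin_ms
    )
    cyc = average_eyes(clean)
    return epoch_to_cue(cyc, trials, window_ms)
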