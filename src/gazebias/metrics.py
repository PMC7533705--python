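"""Descriptive gaze measures: towardness, the fixation-trial filter, and
gaze-density maps.

Towardness compresses the left/right gaze bias into one value per time point:
per participant and condition, the trial-average horizontal gaze following
cues associated with right-coded items minus that following left-coded items,
divided by 2. Positive towardness means gaze drifts toward the coded item's
memorized location. Side coding is *match-coded* (by the cue-feature-matching
item) in null blocks and *goal-coded* (by the to-be-probed item) in pro/anti
blocks.

Trial-average traces are smoothed with a 25-ms-SD Gaussian before the
left/right subtraction; by linearity the order does not change the estimate.
The ±50% fixation filter keeps only trials whose normalized gaze stayed
within ±50% of fixation on both axes throughout encoding → probe. Density
maps pool raw samples (no trial averaging, no ±50% filter) from the
400–1,000-ms post-cue window on a 1% grid and smooth with a 10%-SD 2-D
Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .containers import Epochs

GOAL_CODED = "goal-coded"
MATCH_CODED = "match-coded"

#: side-coding scheme required per block type
SCHEME_FOR_BLOCK = {"pro": GOAL_CODED, "anti": GOAL_CODED, "null": MATCH_CODED}


@dataclass
class TowardnessTimecourse:
    """Smoothed towardness vs. time for one participant × condition."""

    participant: int
    condition: str
    time_ms: np.ndarray
    values: np.ndarray
    n_left: int
    n_right: int


@dataclass
class DensityMap:
    """2-D gaze density (or signed density difference) over [−100, 100]²."""

    x_centers: np.ndarray
    y_centers: np.ndarray
    values: np.ndarray
    n_samples: int = 0
    signed: bool = False

    def to_frame(self) -> pd.DataFrame:
        xg, yg = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return pd.DataFrame(
            {"x_pct": xg.ravel(), "y_pct": yg.ravel(), "density": self.values.ravel()}
        )


def assign_side(trials: pd.DataFrame, scheme: str) -> pd.Series:
    """Coded side ('left'/'right') per trial under the given scheme.

    ``goal-coded``: side of the to-be-probed item (pro/anti blocks only; for
    anti cues this is the item NOT matching the cue feature).
    ``match-coded``: side of the cue-feature-matching item (null blocks only).
    Raises on a scheme/block-type mismatch or on neutral trials (which have
    no feature-matching item).
    """
    if scheme not in (GOAL_CODED, MATCH_CODED):
        raise ValueError(f"unknown scheme {scheme!r}")
    if (trials["condition"] == "neutral").any():
        raise ValueError("neutral trials have no coded side; filter them out")
    expected = trials["block_type"].map(SCHEME_FOR_BLOCK)
    if (expected != scheme).any():
        bad = trials.loc[expected != scheme, "block_type"].unique()
        raise ValueError(
            f"scheme {scheme!r} does not apply to block types {bad.tolist()}"
        )
    if scheme == GOAL_CODED:
        return trials["probed_side"].rename("side")
    match_left = trials["cue_color"] == trials["left_color"]
    match_right = trials["cue_color"] == trials["right_color"]
    if not (match_left ^ match_right).all():
        raise ValueError("cue color must match exactly one item in null blocks")
    return pd.Series(
        np.where(match_left, "left", "right"), index=trials.index, name="side"
    )


def filter_fixation_trials(
    epochs: Epochs,
    bound_pct: float = 50.0,
    span_ms: tuple[float, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Inclusion mask for the ±``bound_pct`` fixation filter.

    A trial is included iff |x| and |y| stay ≤ bound over ``span_ms``
    (default: the full epoch extent, which should cover encoding → probe)
    and the trial was not flagged invalid upstream. Returns (mask, retained
    fraction).
    """
    t = epochs.time_ms
    if span_ms is None:
        sel = slice(None)
    else:
        sel = (t >= span_ms[0]) & (t <= span_ms[1])
    with np.errstate(invalid="ignore"):
        ok = (
            (np.nanmax(np.abs(epochs.x[:, sel]), axis=1) <= bound_pct)
            & (np.nanmax(np.abs(epochs.y[:, sel]), axis=1) <= bound_pct)
        )
    not_invalid = ~np.isin(epochs.trial_ids, sorted(epochs.invalid_trials))
    mask = ok & not_invalid
    return mask, float(mask.mean()) if len(mask) else float("nan")


def smooth_gaussian(
    values: np.ndarray, sd_ms: float = 25.0, axis: int = -1
) -> np.ndarray:
    """Unit-mass Gaussian smoothing (kernel truncated at ±4 SD, reflect-padded)."""
    if sd_ms <= 0:
        return np.asarray(values, float).copy()
    return gaussian_filter1d(
        np.asarray(values, float), sigma=sd_ms, axis=axis, mode="reflect", truncate=4.0
    )


def towardness(
    epochs: Epochs,
    sides: np.ndarray | pd.Series,
    condition: str = "",
    smoothing_sd_ms: float = 25.0,
) -> TowardnessTimecourse | None:
    """T(t) = (smoothed mean x over right-coded − over left-coded trials) / 2.

    ``sides`` is aligned with ``epochs.trial_ids``. Returns None when either
    side has no trials (condition missing for this participant).
    """
    sides = np.asarray(sides)
    if len(sides) != epochs.n_trials:
        raise ValueError("sides must align with epochs.trial_ids")
    right = sides == "right"
    left = sides == "left"
    if right.sum() == 0 or left.sum() == 0:
        return None
    mean_r = smooth_gaussian(epochs.x[right].mean(axis=0), smoothing_sd_ms)
    mean_l = smooth_gaussian(epochs.x[left].mean(axis=0), smoothing_sd_ms)
    return TowardnessTimecourse(
        participant=epochs.participant,
        condition=condition,
        time_ms=epochs.time_ms.copy(),
        values=(mean_r - mean_l) / 2.0,
        n_left=int(left.sum()),
        n_right=int(right.sum()),
    )


def _grid(bin_pct: float) -> np.ndarray:
    half = bin_pct / 2.0
    return np.arange(-100.0 - half, 100.0 + half + 1e-9, bin_pct)


def density_map(
    epochs: Epochs,
    window_ms: tuple[float, float] = (400.0, 1000.0),
    bin_pct: float = 1.0,
    smooth_sd_pct: float = 10.0,
) -> DensityMap:
    """Gaze-position density over [−100, 100]², pooled across time and trials.

    Counts on a ``bin_pct`` grid divided by the *total* number of samples in
    the window (samples beyond ±100% fall outside the grid but still count
    toward the total), then smoothed with a 2-D Gaussian of SD
    ``smooth_sd_pct`` per axis.
    """
    t = epochs.time_ms
    sel = (t >= window_ms[0]) & (t <= window_ms[1])
    if not sel.any() or epochs.n_trials == 0:
        raise ValueError("empty density window")
    x = epochs.x[:, sel].ravel()
    y = epochs.y[:, sel].ravel()
    finite = np.isfinite(x) & np.isfinite(y)
    x, y = x[finite], y[finite]
    edges = _grid(bin_pct)
    counts, _, _ = np.histogram2d(x, y, bins=(edges, edges))
    total = len(x)
    if total == 0:
        raise ValueError("no finite samples in density window")
    dens = counts / total
    if smooth_sd_pct > 0:
        dens = gaussian_filter(
            dens, sigma=smooth_sd_pct / bin_pct, mode="constant", truncate=4.0
        )
    centers = (edges[:-1] + edges[1:]) / 2.0
    return DensityMap(
        x_centers=centers, y_centers=centers, values=dens, n_samples=total
    )


def density_difference(left_cued: DensityMap, right_cued: DensityMap) -> DensityMap:
    """Signed difference map: density(left-cued) − density(right-cued)."""
    if left_cued.values.shape != right_cued.values.shape:
        raise ValueError("density maps have different grids")
    return DensityMap(
        x_centers=left_cued.x_centers.copy(),
        y_centers=left_cued.y_centers.copy(),
        values=left_cued.values - right_cued.values,
        n_samples=left_cued.n_samples + right_cued.n_samples,
        signed=True,
    )


def plot_towardness(
    curves: dict[str, "ConditionCurves"], path=None, title: str = ""
):
    """Quick-look plot of group towardness per condition (optional export).

    Requires matplotlib; returns the figure, saving to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, cc in curves.items():
        stack = cc.stack()
        mean = stack.mean(axis=0)
        sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
        ax.plot(cc.time_ms, mean, label=name)
        ax.fill_between(cc.time_ms, mean - sem, mean + sem, alpha=0.25)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time after retrocue (ms)")
    ax.set_ylabel("towardness (%)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


@dataclass
class ConditionCurves:
    """Per-participant towardness curves stacked for group inference."""

    condition: str
    time_ms: np.ndarray
    participants: list[int] = field(default_factory=list)
    curves: list[np.ndarray] = field(default_factory=list)

    def add(self, tc: TowardnessTimecourse) -> None:
        self.participants.append(tc.participant)
        self.curves.append(tc.values)

    def stack(self) -> np.ndarray:
        return np.vstack(self.curves)

    def group_mean(self) -> np.ndarray:
        return self.stack().mean(axis=0)
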