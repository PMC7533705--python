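"""Per-participant linear maps from raw gaze units to normalized % units.

±100% corresponds to the calibration points at the memory-item centers
(±5.7° visual angle). The map is estimated from the interleaved 7-point
calibration modules: per-position median gaze over 500–1000 ms after point
onset, horizontal gain from the middle-row eccentric points, vertical gain
from the top vs. bottom rows (raw coordinates are screen-down-positive).
Each task block is normalized with the model from the nearest preceding
module; the first three blocks use the first module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Epochs

# nominal normalized coordinates of the 7-point layout (y down-positive);
# the eccentric columns/rows sit at the memory-item eccentricity (±100%)
CALIB_POSITIONS_NOMINAL = {
    "left-top": (-100.0, -100.0),
    "left-middle": (-100.0, 0.0),
    "left-bottom": (-100.0, 100.0),
    "right-top": (100.0, -100.0),
    "right-middle": (100.0, 0.0),
    "right-bottom": (100.0, 100.0),
    "center": (0.0, 0.0),
}

TOP_ROW = ("left-top", "right-top")
BOTTOM_ROW = ("left-bottom", "right-bottom")
REQUIRED_POSITIONS = (
    "center",
    "left-middle",
    "right-middle",
    "left-top",
    "right-top",
    "left-bottom",
    "right-bottom",
)


@dataclass
class CalibrationModel:
    """Affine raw→% map: pct = (raw − offset) / gain, gain in raw units per %."""

    participant: int
    module: int
    x_offset: float
    x_gain: float
    y_offset: float
    y_gain: float
    window_ms: tuple[float, float] = (500.0, 1000.0)

    def x_to_pct(self, x_raw: np.ndarray) -> np.ndarray:
        return (np.asarray(x_raw) - self.x_offset) / self.x_gain

    def y_to_pct(self, y_raw: np.ndarray) -> np.ndarray:
        return (np.asarray(y_raw) - self.y_offset) / self.y_gain


def position_medians(
    calib: pd.DataFrame, window_ms: tuple[float, float] = (500.0, 1000.0)
) -> pd.DataFrame:
    """Median cyclopean gaze per calibration position, pooled across visits.

    Uses samples in ``window_ms`` after each calibration-point onset (time_ms
    is relative to visit onset in the calibration table).
    """
    w = calib[(calib["time_ms"] >= window_ms[0]) & (calib["time_ms"] < window_ms[1])]
    if w.empty:
        raise ValueError("no calibration samples in the median window")
    x = (w["x_left"].to_numpy() + w["x_right"].to_numpy()) / 2.0
    y = (w["y_left"].to_numpy() + w["y_right"].to_numpy()) / 2.0
    med = (
        pd.DataFrame({"position": w["position"].to_numpy(), "x": x, "y": y})
        .groupby("position")
        .median()
    )
    return med


def estimate_calibration(
    calib: pd.DataFrame,
    participant: int | None = None,
    module: int | None = None,
    window_ms: tuple[float, float] = (500.0, 1000.0),
) -> CalibrationModel:
    """Fit one CalibrationModel from one module's sample table.

    Raises if a required position is missing or an estimated gain is not
    strictly positive (a non-positive horizontal gain suggests a left/right
    inversion in the recording).
    """
    if participant is None:
        ids = calib["participant"].unique()
        if len(ids) != 1:
            raise ValueError("pass `participant` when the table holds several")
        participant = int(ids[0])
    if module is None:
        mods = calib["module"].unique() if "module" in calib.columns else [1]
        if len(mods) != 1:
            raise ValueError("pass `module` when the table holds several")
        module = int(mods[0])
    med = position_medians(calib, window_ms)
    missing = [p for p in REQUIRED_POSITIONS if p not in med.index]
    if missing:
        raise ValueError(f"calibration positions missing: {missing}")
    x_offset = float(med.loc["center", "x"])
    y_offset = float(med.loc["center", "y"])
    x_gain = float(med.loc["right-middle", "x"] - med.loc["left-middle", "x"]) / 200.0
    y_gain = (
        float(np.mean([med.loc[p, "y"] for p in BOTTOM_ROW]))
        - float(np.mean([med.loc[p, "y"] for p in TOP_ROW]))
    ) / 200.0
    if x_gain <= 0 or y_gain <= 0:
        raise ValueError(
            f"non-positive gain (x={x_gain:.4g}, y={y_gain:.4g}); "
            "check for axis inversion in the recording"
        )
    return CalibrationModel(
        participant=participant,
        module=module,
        x_offset=x_offset,
        x_gain=x_gain,
        y_offset=y_offset,
        y_gain=y_gain,
        window_ms=window_ms,
    )


def estimate_all(
    calib: pd.DataFrame, window_ms: tuple[float, float] = (500.0, 1000.0)
) -> dict[tuple[int, int], CalibrationModel]:
    """CalibrationModel per (participant, module)."""
    models: dict[tuple[int, int], CalibrationModel] = {}
    for (p, m), grp in calib.groupby(["participant", "module"]):
        models[(int(p), int(m))] = estimate_calibration(
            grp, participant=int(p), module=int(m), window_ms=window_ms
        )
    return models


def module_for_block(block: int) -> int:
    """Nearest preceding calibration module (modules sit after every 3 blocks)."""
    return max((int(block) - 1) // 3, 1)


def normalize(epochs: Epochs, model: CalibrationModel) -> Epochs:
    """Apply one model to all trials of an epoch set (raw → % units)."""
    if model.participant != epochs.participant:
        raise ValueError(
            f"model participant {model.participant} != epochs participant "
            f"{epochs.participant}"
        )
    return Epochs(
        participant=epochs.participant,
        trial_ids=epochs.trial_ids.copy(),
        time_ms=epochs.time_ms.copy(),
        x=model.x_to_pct(epochs.x),
        y=model.y_to_pct(epochs.y),
        valid=epochs.valid.copy(),
        invalid_trials=set(epochs.invalid_trials),
    )


def normalize_by_module(
    epochs: Epochs,
    trials: pd.DataFrame,
    models: dict[tuple[int, int], CalibrationModel],
) -> Epochs:
    """Normalize each trial with the model from its nearest preceding module."""
    block = (
        trials.set_index("trial")["block"].reindex(epochs.trial_ids).to_numpy()
    )
    if np.isnan(block.astype(float)).any():
        raise ValueError("epochs contain trials absent from the trial table")
    p = epochs.participant
    available = sorted(m for (pp, m) in models if pp == p)
    if not available:
        raise ValueError(f"no calibration models for participant {p}")
    x = np.empty_like(epochs.x)
    y = np.empty_like(epochs.y)
    for b in np.unique(block):
        want = module_for_block(int(b))
        # fall back to the closest existing module if a module is missing
        mod = min(available, key=lambda m: (abs(m - want), m))
        model = models[(p, mod)]
        rows = block == b
        x[rows] = model.x_to_pct(epochs.x[rows])
        y[rows] = model.y_to_pct(epochs.y[rows])
    return Epochs(
        participant=p,
        trial_ids=epochs.trial_ids.copy(),
        time_ms=epochs.time_ms.copy(),
        x=x,
        y=y,
        valid=epochs.valid.copy(),
        invalid_trials=set(epochs.invalid_trials),
    )
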