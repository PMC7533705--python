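"""In-memory containers for gaze data.

Dense per-participant arrays (trials × time) are the working representation;
long-format delimited tables with one row per sample are the on-disk exchange
format. Conversion between the two lives here.

Expected long-table columns for binocular gaze:
``participant, trial, time_ms, x_left, y_left, x_right, y_right,
pupil_left, pupil_right`` — time in ms from trial start, strictly increasing
in 1-ms steps within each trial, no duplicate (trial, time_ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GAZE_CHANNELS = ("x_left", "y_left", "x_right", "y_right")
PUPIL_CHANNELS = ("pupil_left", "pupil_right")
ALL_CHANNELS = GAZE_CHANNELS + PUPIL_CHANNELS

GAZE_TABLE_COLUMNS = ("participant", "trial", "time_ms") + ALL_CHANNELS


@dataclass
class BinocularGaze:
    """1000-Hz binocular sample streams for one participant, dense over trials.

    All trials share the common ``time_ms`` grid (ms from trial start); each
    channel is an array of shape ``(n_trials, n_times)``.
    """

    participant: int
    trial_ids: np.ndarray
    time_ms: np.ndarray
    x_left: np.ndarray
    y_left: np.ndarray
    x_right: np.ndarray
    y_right: np.ndarray
    pupil_left: np.ndarray
    pupil_right: np.ndarray
    invalid_trials: set[int] = field(default_factory=set)

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)

    @property
    def n_times(self) -> int:
        return len(self.time_ms)

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def copy(self) -> "BinocularGaze":
        return BinocularGaze(
            participant=self.participant,
            trial_ids=self.trial_ids.copy(),
            time_ms=self.time_ms.copy(),
            **{c: self.channel(c).copy() for c in ALL_CHANNELS},
            invalid_trials=set(self.invalid_trials),
        )

    def to_frame(self) -> pd.DataFrame:
        n_tr, n_t = self.n_trials, self.n_times
        out = {
            "participant": np.full(n_tr * n_t, self.participant),
            "trial": np.repeat(self.trial_ids, n_t),
            "time_ms": np.tile(self.time_ms, n_tr),
        }
        for c in ALL_CHANNELS:
            out[c] = self.channel(c).ravel()
        return pd.DataFrame(out)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinocularGaze":
        missing = [c for c in GAZE_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"gaze table missing columns: {missing}")
        participants = df["participant"].unique()
        if len(participants) != 1:
            raise ValueError(
                "one BinocularGaze holds one participant; got "
                f"{len(participants)} — split the table first"
            )
        if df.duplicated(["trial", "time_ms"]).any():
            bad = df[df.duplicated(["trial", "time_ms"])].iloc[0]
            raise ValueError(
                f"duplicate (trial, time_ms) = ({bad['trial']}, {bad['time_ms']})"
            )
        df = df.sort_values(["trial", "time_ms"], kind="stable")
        trial_ids = df["trial"].unique()
        counts = df.groupby("trial", sort=False).size()
        if counts.nunique() != 1:
            raise ValueError("trials have unequal sample counts; common grid required")
        n_t = int(counts.iloc[0])
        time = df["time_ms"].to_numpy()[:n_t].astype(float)
        if not np.allclose(np.diff(time), 1.0):
            raise ValueError("time must advance in 1-ms steps within each trial")
        chans = {
            c: df[c].to_numpy().reshape(len(trial_ids), n_t).astype(float)
            for c in ALL_CHANNELS
        }
        return cls(
            participant=int(participants[0]),
            trial_ids=trial_ids.astype(int),
            time_ms=time,
            **chans,
        )


@dataclass
class CyclopeanGaze:
    """Eye-averaged gaze for one participant; ``valid`` marks usable samples."""

    participant: int
    trial_ids: np.ndarray
    time_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    invalid_trials: set[int] = field(default_factory=set)

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)


@dataclass
class Epochs:
    """Cue-locked gaze epochs on a shared time axis (ms from retrocue onset)."""

    participant: int
    trial_ids: np.ndarray
    time_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    invalid_trials: set[int] = field(default_factory=set)

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)

    def subset(self, mask: np.ndarray) -> "Epochs":
        return Epochs(
            participant=self.participant,
            trial_ids=self.trial_ids[mask],
            time_ms=self.time_ms,
            x=self.x[mask],
            y=self.y[mask],
            valid=self.valid[mask],
            invalid_trials=set(self.invalid_trials),
        )
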