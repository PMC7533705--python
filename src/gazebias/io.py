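"""Delimited-text table I/O and schema validation.

All exchange formats are tab-separated text with a one-line header. EyeLink
ASC ingestion is out of scope; external converters should produce these
tables (column contract in :mod:`gazebias.containers` and below).

Trial-table columns: ``participant, trial, block, block_type, condition,
cue_color, left_color, right_color, left_ori, right_ori, probed_side,
target_ori, nontarget_ori, report_ori, rt_ms, encoding_onset_ms,
cue_onset_ms, probe_onset_ms``.

Calibration-table columns: ``participant, module, position, visit, time_ms``
plus the six binocular channels; ``time_ms`` is relative to calibration-point
onset within each visit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ALL_CHANNELS, GAZE_TABLE_COLUMNS, BinocularGaze

TRIAL_REQUIRED = (
    "participant",
    "trial",
    "block",
    "block_type",
    "condition",
    "cue_color",
    "left_color",
    "right_color",
    "probed_side",
    "target_ori",
    "nontarget_ori",
    "report_ori",
    "rt_ms",
    "encoding_onset_ms",
    "cue_onset_ms",
    "probe_onset_ms",
)
CALIB_REQUIRED = ("participant", "module", "position", "visit", "time_ms") + ALL_CHANNELS
BLOCK_TYPES = {"pro", "anti", "null"}


def read_table(path: str | Path) -> pd.DataFrame:
    # keep_default_na: "null" is a block type, not a missing value
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_gaze(path: str | Path) -> dict[int, BinocularGaze]:
    """Load a gaze table and split it into per-participant dense containers."""
    df = read_table(path)
    return {
        int(p): BinocularGaze.from_frame(grp)
        for p, grp in df.groupby("participant")
    }


def validate_tables(
    gaze_path: str | Path | None = None,
    trials_path: str | Path | None = None,
    calibration_path: str | Path | None = None,
) -> dict:
    """Schema checks with first-failure locations; machine-readable result.

    Checks column presence, time monotonicity at 1-ms steps, duplicate
    (participant, trial, time) rows, block-type vocabulary, and per-participant
    row counts. Returns ``{"pass": bool, "failures": [...], "counts": {...}}``.
    """
    failures: list[dict] = []
    counts: dict = {}

    def fail(table: str, check: str, location: str) -> None:
        failures.append({"table": table, "check": check, "location": location})

    if gaze_path is not None:
        df = read_table(gaze_path)
        missing = [c for c in GAZE_TABLE_COLUMNS if c not in df.columns]
        if missing:
            fail("gaze", "missing columns", str(missing))
        else:
            dup = df.duplicated(["participant", "trial", "time_ms"])
            if dup.any():
                row = df[dup].iloc[0]
                fail(
                    "gaze",
                    "duplicate (trial, time)",
                    f"participant {row['participant']} trial {row['trial']} "
                    f"time {row['time_ms']} (row {int(np.flatnonzero(dup)[0])})",
                )
            for (p, tr), grp in df.groupby(["participant", "trial"]):
                dt = np.diff(grp["time_ms"].to_numpy())
                if len(dt) and not np.allclose(dt, 1.0):
                    fail(
                        "gaze",
                        "time not strictly increasing in 1-ms steps",
                        f"participant {p} trial {tr}",
                    )
                    break
            counts["gaze_rows_per_participant"] = (
                df.groupby("participant").size().to_dict()
            )

    if trials_path is not None:
        df = read_table(trials_path)
        missing = [c for c in TRIAL_REQUIRED if c not in df.columns]
        if missing:
            fail("trials", "missing columns", str(missing))
        else:
            bad = ~df["block_type"].isin(BLOCK_TYPES)
            if bad.any():
                fail(
                    "trials",
                    "unknown block_type",
                    f"row {int(np.flatnonzero(bad)[0])}: "
                    f"{df.loc[bad, 'block_type'].iloc[0]!r}",
                )
            dup = df.duplicated(["participant", "trial"])
            if dup.any():
                fail("trials", "duplicate trial id", f"row {int(np.flatnonzero(dup)[0])}")
            counts["trials_per_participant"] = (
                df.groupby("participant").size().to_dict()
            )

    if calibration_path is not None:
        df = read_table(calibration_path)
        missing = [c for c in CALIB_REQUIRED if c not in df.columns]
        if missing:
            fail("calibration", "missing columns", str(missing))
        else:
            counts["calibration_modules_per_participant"] = (
                df.groupby("participant")["module"].nunique().to_dict()
            )

    return {"pass": not failures, "failures": failures, "counts": counts}
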