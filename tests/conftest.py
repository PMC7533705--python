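import numpy as np
import pandas as pd
import pytest

from gazebias.config import AnalysisConfig, GeneratorConfig
from gazebias.containers import BinocularGaze


def make_gaze(
    x: np.ndarray,
    pupil: np.ndarray | None = None,
    participant: int = 1,
    y: np.ndarray | None = None,
) -> BinocularGaze:
    """Tiny binocular container with identical eyes, for unit tests."""
    x = np.atleast_2d(np.asarray(x, float))
    y = x.copy() if y is None else np.atleast_2d(np.asarray(y, float))
    pupil = (
        np.full_like(x, 1000.0) if pupil is None else np.atleast_2d(np.asarray(pupil, float))
    )
    n_tr, n_t = x.shape
    return BinocularGaze(
        participant=participant,
        trial_ids=np.arange(1, n_tr + 1),
        time_ms=np.arange(n_t, dtype=float),
        x_left=x.copy(),
        y_left=y.copy(),
        x_right=x.copy(),
        y_right=y.copy(),
        pupil_left=pupil.copy(),
        pupil_right=pupil.copy(),
    )


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """3 participants × 2 superblocks (96 trials), fixed seed."""
    return GeneratorConfig(n_participants=3, n_superblocks=2, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_cfg):
    from gazebias.synth import generate_experiment

    return generate_experiment(small_cfg)


@pytest.fixture(scope="session")
def analysis_cfg() -> AnalysisConfig:
    return AnalysisConfig(n_permutations=500, seed=5)


@pytest.fixture(scope="session")
def small_study(small_cfg, analysis_cfg):
    """Full pipeline result on the small synthetic experiment."""
    from gazebias.pipeline import analyze_participant, analyze_study
    from gazebias.synth import generate_participant

    results = []
    for p in range(1, small_cfg.n_participants + 1):
        gaze, trials, calib, _ = generate_participant(small_cfg, p)
        results.append(analyze_participant(gaze, trials, calib, analysis_cfg))
    return analyze_study(results, analysis_cfg)


def trial_row(
    condition: str,
    cue_color: str,
    left_color: str,
    right_color: str,
    probed_side: str,
    trial: int = 1,
    **kw,
) -> dict:
    block_type = {"pro": "pro", "anti": "anti"}.get(condition, "null")
    row = {
        "participant": 1,
        "trial": trial,
        "block": 1,
        "block_type": block_type,
        "condition": condition,
        "cue_color": cue_color,
        "left_color": left_color,
        "right_color": right_color,
        "probed_side": probed_side,
        "target_ori": 10,
        "nontarget_ori": 100,
        "report_ori": 12.0,
        "rt_ms": 700.0,
        "encoding_onset_ms": 0.0,
        "cue_onset_ms": 1000.0,
        "probe_onset_ms": 3000.0,
    }
    row.update(kw)
    return row


def trials_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)
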