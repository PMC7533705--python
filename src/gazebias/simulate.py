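"""Monte-Carlo validation drivers: run the real generator → preprocess →
calibrate → filter → towardness chain many times to characterize the
analysis (type-I error calibration, onset-latency recovery, competition
additivity). Useful for power analysis and for verifying that the inference
machinery behaves as advertised before pointing it at real data.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .calibration import estimate_all, normalize_by_module
from .config import AnalysisConfig, GeneratorConfig
from .containers import Epochs
from .inference import cluster_test, onset_latency
from .metrics import (
    GOAL_CODED,
    MATCH_CODED,
    assign_side,
    filter_fixation_trials,
    towardness,
)
from .preprocess import preprocess_participant
from .synth import (
    generate_calibration,
    generate_participant_gaze,
    make_trials,
    simulate_behavior,
)

CONDITION_SCHEME = {"null": MATCH_CODED, "pro": GOAL_CODED, "anti": GOAL_CODED}


def participant_towardness(
    cfg: GeneratorConfig,
    acfg: AnalysisConfig,
    participant: int,
    conditions: tuple[str, ...] = ("null", "pro", "anti"),
) -> dict[str, np.ndarray | None]:
    """One participant's towardness curve per condition via the full chain."""
    trials = make_trials(cfg, participant)
    trials, truth = simulate_behavior(cfg, trials, participant)
    gaze, _ = generate_participant_gaze(
        cfg, trials, participant, swap=truth["swap"].to_numpy()
    )
    enc_rel = cfg.encoding_onset_ms - cfg.cue_onset_ms
    probe_rel = cfg.probe_onset_ms - cfg.cue_onset_ms
    w0, w1 = acfg.epoch_window_ms
    wide = (min(enc_rel, w0), max(probe_rel, w1))
    epochs = preprocess_participant(
        gaze,
        trials,
        window_ms=wide,
        merge_gap_ms=acfg.blink_merge_gap_ms,
        pad_ms=acfg.blink_pad_ms,
        flank_ms=acfg.spline_flank_ms,
        anchor_bin_ms=acfg.spline_anchor_bin_ms,
    )
    models = estimate_all(
        generate_calibration(cfg, participant), window_ms=acfg.calib_median_window_ms
    )
    norm = normalize_by_module(epochs, trials, models)
    mask, _ = filter_fixation_trials(
        norm, bound_pct=acfg.fixation_bound_pct, span_ms=(enc_rel, probe_rel)
    )
    sel = (norm.time_ms >= w0) & (norm.time_ms <= w1)
    analysis = Epochs(
        participant=participant,
        trial_ids=norm.trial_ids,
        time_ms=norm.time_ms[sel],
        x=norm.x[:, sel],
        y=norm.y[:, sel],
        valid=norm.valid[:, sel],
        invalid_trials=set(norm.invalid_trials),
    )
    out: dict[str, np.ndarray | None] = {"time_ms": analysis.time_ms}
    for cond in conditions:
        in_cond = (
            (trials["block_type"] == "null")
            if cond == "null"
            else (trials["condition"] == cond)
        ).to_numpy()
        use = in_cond & mask
        sides = assign_side(trials[in_cond], CONDITION_SCHEME[cond]).to_numpy()
        tc = towardness(
            analysis.subset(use),
            sides[mask[in_cond]],
            cond,
            acfg.smoothing_sd_ms,
        )
        out[cond] = None if tc is None else tc.values
    return out


def study_towardness(
    cfg: GeneratorConfig,
    acfg: AnalysisConfig,
    conditions: tuple[str, ...] = ("null", "pro", "anti"),
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Stacked (participants × time) towardness per condition for one study."""
    curves: dict[str, list[np.ndarray]] = {c: [] for c in conditions}
    time_ms = None
    for p in range(1, cfg.n_participants + 1):
        res = participant_towardness(cfg, acfg, p, conditions)
        time_ms = res["time_ms"]
        for c in conditions:
            if res[c] is not None:
                curves[c].append(res[c])
    assert time_ms is not None
    return time_ms, {c: np.vstack(v) for c, v in curves.items()}


def _null_config(base: GeneratorConfig, seed: int) -> GeneratorConfig:
    cfg = copy.deepcopy(base)
    cfg.voluntary_bias.amplitude_pct = 0.0
    cfg.involuntary_bias.amplitude_pct = 0.0
    cfg.seed = seed
    return cfg


@dataclass
class TypeOneResult:
    n_replicates: int
    n_false_positive: int

    @property
    def rate(self) -> float:
        return self.n_false_positive / self.n_replicates


def type_one_error(
    n_replicates: int = 500,
    n_participants: int = 25,
    n_perm: int = 1000,
    seed: int = 0,
    base_cfg: GeneratorConfig | None = None,
    acfg: AnalysisConfig | None = None,
    trials_per_block: int = 4,
    condition: str = "null",
) -> TypeOneResult:
    """False-positive rate of the one-sample cluster test under the null.

    Replicate experiments are generated with both bias amplitudes at zero;
    a replicate counts as a false positive when any cluster reaches p < 0.05.
    Trial counts per participant are kept small (they shift curve noise, not
    the calibration of the across-participant t statistics).
    """
    base = base_cfg or GeneratorConfig(
        n_participants=n_participants,
        n_superblocks=1,
        trials_per_block=trials_per_block,
    )
    acfg = acfg or AnalysisConfig(epoch_window_ms=(0.0, 2000.0))
    hits = 0
    rng = np.random.SeedSequence(seed)
    rep_seeds = rng.generate_state(2 * n_replicates) & 0x7FFFFFFF
    for i in range(n_replicates):
        cfg = _null_config(base, int(rep_seeds[2 * i]))
        time_ms, curves = study_towardness(cfg, acfg, (condition,))
        res = cluster_test(
            curves[condition],
            time_ms,
            n_perm=n_perm,
            seed=int(rep_seeds[2 * i + 1]),
        )
        if any(c.p < 0.05 for c in res.clusters):
            hits += 1
    return TypeOneResult(n_replicates=n_replicates, n_false_positive=hits)


@dataclass
class RecoveryResult:
    pro_onsets: np.ndarray
    anti_onsets: np.ndarray

    def pro_within(self, target_ms: float, tol_ms: float = 50.0) -> int:
        ok = np.isfinite(self.pro_onsets) & (
            np.abs(self.pro_onsets - target_ms) <= tol_ms
        )
        return int(ok.sum())

    def anti_later(self) -> int:
        ok = (
            np.isfinite(self.pro_onsets)
            & np.isfinite(self.anti_onsets)
            & (self.anti_onsets > self.pro_onsets)
        )
        return int(ok.sum())


def onset_recovery(
    n_replicates: int = 100,
    n_participants: int = 25,
    seed: int = 0,
    base_cfg: GeneratorConfig | None = None,
    acfg: AnalysisConfig | None = None,
    n_superblocks: int = 5,
) -> RecoveryResult:
    """Recovery of pro/anti fractional-peak onsets over replicate studies."""
    base = base_cfg or GeneratorConfig(
        n_participants=n_participants, n_superblocks=n_superblocks
    )
    acfg = acfg or AnalysisConfig(epoch_window_ms=(0.0, 2000.0))
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) & 0x7FFFFFFF
    pro_onsets, anti_onsets = [], []
    for i in range(n_replicates):
        cfg = copy.deepcopy(base)
        cfg.seed = int(rep_seeds[i])
        time_ms, curves = study_towardness(cfg, acfg, ("pro", "anti"))
        pro_onsets.append(
            onset_latency(
                time_ms,
                curves["pro"].mean(axis=0),
                acfg.onset_fraction,
                acfg.onset_window_ms,
            )
        )
        anti_onsets.append(
            onset_latency(
                time_ms,
                curves["anti"].mean(axis=0),
                acfg.onset_fraction,
                acfg.onset_window_ms,
            )
        )
    return RecoveryResult(
        pro_onsets=np.array(pro_onsets), anti_onsets=np.array(anti_onsets)
    )
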