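"""Synthetic pro/anti/null retrocue experiments with known ground truth.

The generator emulates the study design end to end: per participant,
``n_superblocks`` superblocks each containing one pro-, one anti-, and one
null-block (random order) of ``trials_per_block`` trials; two colored oriented
bars at ±100% (≡ ±5.7° visual angle); a retrocue 1 s after encoding and a
probe 2 s after the cue; 1000-Hz binocular gaze; interleaved 7-point
calibration modules after every three blocks.

Gaze model (normalized % units, additive):

    x(t) = OU drift + voluntary(t) · goal_sign + involuntary(t) · match_sign
           + measurement noise (per eye)

* OU drift — discretized mean-reverting (Ornstein–Uhlenbeck) process; fixation
  is the attractor, stationary SD set by (diffusion, reversion rate).
* voluntary — ramp-to-plateau template toward the goal (to-be-probed) item;
  present in pro and anti blocks only.
* involuntary — ramp then exponential decay toward the cue-feature-matching
  item; present in pro, anti, and null blocks. In pro trials both components
  point the same way, in anti trials opposite ways.
* blinks — Poisson-placed, both pupils set to 0 and gaze railed off-screen;
  never overlapping trial boundaries.

Reports are drawn in the 180°-periodic orientation space as von Mises deviates
on the doubled-angle circle, with condition-dependent swap (wrong item) and
uniform-guess probabilities; RTs are shifted-lognormal with an informativeness
benefit. Output is bit-identical for identical (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import GeneratorConfig
from .containers import BinocularGaze

BLOCK_TYPES = ("pro", "anti", "null")
COLORS = ("green", "purple")
NEUTRAL_COLOR = "gray"

from .calibration import CALIB_POSITIONS_NOMINAL as CALIB_POSITIONS

TRIAL_COLUMNS = [
    "participant",
    "trial",
    "block",
    "block_type",
    "condition",
    "cue_color",
    "left_color",
    "right_color",
    "left_ori",
    "right_ori",
    "probed_side",
    "target_ori",
    "nontarget_ori",
    "report_ori",
    "rt_ms",
    "encoding_onset_ms",
    "cue_onset_ms",
    "probe_onset_ms",
]


@dataclass
class ParticipantGeometry:
    """Ground-truth raw-unit map for one participant (raw = offset + gain · %)."""

    x_gain: float
    y_gain: float
    x_offset: float
    y_offset: float


@dataclass
class Experiment:
    """One generated experiment: gaze per participant plus combined tables."""

    gaze: dict[int, BinocularGaze]
    trials: pd.DataFrame
    calibration: pd.DataFrame
    truth: pd.DataFrame


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def participant_geometry(cfg: GeneratorConfig, participant: int) -> ParticipantGeometry:
    g = cfg.calibration
    r = _rng(cfg.seed, participant, 3)
    jit = r.normal(size=4)
    return ParticipantGeometry(
        x_gain=g.x_gain_mean + g.gain_jitter_sd * jit[0],
        y_gain=g.y_gain_mean + g.gain_jitter_sd * jit[1],
        x_offset=g.x_offset_mean + g.offset_jitter_sd * jit[2],
        y_offset=g.y_offset_mean + g.offset_jitter_sd * jit[3],
    )


def _ou(rng: np.random.Generator, shape: tuple[int, int], theta: float, diffusion: float) -> np.ndarray:
    """Discrete OU (AR(1)) sample paths at 1-ms steps, started stationary."""
    a = 1.0 - theta
    sigma = np.sqrt(diffusion)
    noise = sigma * rng.standard_normal(shape)
    if abs(a) < 1.0 and theta > 0:
        sd0 = sigma / np.sqrt(1.0 - a * a)
        noise[:, 0] = sd0 * rng.standard_normal(shape[0])
    out = lfilter([1.0], [1.0, -a], noise, axis=1)
    return np.asarray(out)


def _block_plan(cfg: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    plan: list[str] = []
    for _ in range(cfg.n_superblocks):
        order = list(BLOCK_TYPES)
        rng.shuffle(order)
        plan.extend(order)
    return plan


def make_trials(cfg: GeneratorConfig, participant: int) -> pd.DataFrame:
    """Design + behavior table for one participant (one row per trial)."""
    rng = _rng(cfg.seed, participant, 0)
    plan = _block_plan(cfg, rng)
    n_per = cfg.trials_per_block
    rows: list[dict] = []
    trial_id = 0
    for block_idx, btype in enumerate(plan, start=1):
        sides = np.array(["left", "right"]).repeat(n_per // 2)
        if len(sides) < n_per:  # odd block size: extra side at random
            sides = np.append(sides, rng.choice(["left", "right"]))
        rng.shuffle(sides)
        # null blocks: 50% match / 50% nonmatch, balanced then shuffled
        match_flags = np.array([True, False]).repeat(n_per // 2)
        if len(match_flags) < n_per:
            match_flags = np.append(match_flags, rng.random() < 0.5)
        rng.shuffle(match_flags)
        n_neutral = int(round(cfg.neutral_fraction * n_per)) if cfg.include_neutral else 0
        neutral_flags = np.zeros(n_per, bool)
        neutral_flags[:n_neutral] = True
        rng.shuffle(neutral_flags)
        for i in range(n_per):
            trial_id += 1
            left_color, right_color = (
                COLORS if rng.random() < 0.5 else COLORS[::-1]
            )
            left_ori = int(rng.integers(0, 180))
            right_ori = int(rng.integers(0, 180))
            probed = sides[i]
            probed_color = left_color if probed == "left" else right_color
            other_color = right_color if probed == "left" else left_color
            if neutral_flags[i]:
                condition, cue_color = "neutral", NEUTRAL_COLOR
            elif btype == "pro":
                condition, cue_color = "pro", probed_color
            elif btype == "anti":
                condition, cue_color = "anti", other_color
            else:
                if match_flags[i]:
                    condition, cue_color = "match", probed_color
                else:
                    condition, cue_color = "nonmatch", other_color
            rows.append(
                {
                    "participant": participant,
                    "trial": trial_id,
                    "block": block_idx,
                    "block_type": btype,
                    "condition": condition,
                    "cue_color": cue_color,
                    "left_color": left_color,
                    "right_color": right_color,
                    "left_ori": left_ori,
                    "right_ori": right_ori,
                    "probed_side": probed,
                    "target_ori": left_ori if probed == "left" else right_ori,
                    "nontarget_ori": right_ori if probed == "left" else left_ori,
                    "encoding_onset_ms": cfg.encoding_onset_ms,
                    "cue_onset_ms": cfg.cue_onset_ms,
                    "probe_onset_ms": cfg.probe_onset_ms,
                }
            )
    return pd.DataFrame(rows)


def _condition_kappa(cfg: GeneratorConfig, condition: np.ndarray) -> np.ndarray:
    b = cfg.behavior
    kappa = np.where(
        np.isin(condition, ["pro", "match"]), b.kappa_match, b.kappa_nonmatch
    ).astype(float)
    informative = np.isin(condition, ["pro", "anti"])
    kappa[informative] *= b.kappa_informative_gain
    return kappa


def simulate_behavior(
    cfg: GeneratorConfig, trials: pd.DataFrame, participant: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw reports and RTs; returns (trials with report/rt, latent truth)."""
    rng = _rng(cfg.seed, participant, 1)
    b = cfg.behavior
    n = len(trials)
    condition = trials["condition"].to_numpy()
    kappa = _condition_kappa(cfg, condition)
    swap_p = np.array([b.swap_prob.get(c, 0.0) for c in condition])
    u = rng.random(n)
    guess = u < b.guess_prob
    swap = ~guess & (u < b.guess_prob + swap_p)
    # error on the doubled-angle circle, halved back into 180° space
    err2 = rng.vonmises(0.0, kappa)
    err_deg = np.degrees(err2) / 2.0
    center = np.where(
        swap, trials["nontarget_ori"].to_numpy(), trials["target_ori"].to_numpy()
    ).astype(float)
    report = np.mod(center + err_deg, 180.0)
    report[guess] = rng.uniform(0.0, 180.0, guess.sum())
    informative = np.isin(condition, ["pro", "anti"])
    mu = np.where(informative, b.rt_mu_informative, b.rt_mu_uninformative)
    is_match = np.isin(condition, ["pro", "match"])
    rt = (
        b.rt_shift_ms
        - b.rt_match_benefit_ms * is_match
        + np.exp(rng.normal(mu, b.rt_sigma))
    )
    out = trials.copy()
    out["report_ori"] = report
    out["rt_ms"] = rt
    truth = pd.DataFrame(
        {
            "participant": participant,
            "trial": trials["trial"].to_numpy(),
            "condition": condition,
            "swap": swap,
            "guess": guess,
            "true_error_deg": err_deg,
        }
    )
    return out, truth


def _bias_signs(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial signs (+1 = right) for the voluntary and involuntary components.

    Voluntary follows the goal (to-be-probed) item, informative blocks only;
    involuntary follows the cue-feature-matching item, absent for neutral cues.
    """
    probed_right = (trials["probed_side"] == "right").to_numpy()
    goal = np.where(probed_right, 1.0, -1.0)
    cue_matches_right = (trials["cue_color"] == trials["right_color"]).to_numpy()
    match = np.where(cue_matches_right, 1.0, -1.0)
    informative = trials["condition"].isin(["pro", "anti"]).to_numpy()
    neutral = (trials["condition"] == "neutral").to_numpy()
    vol_sign = np.where(informative, goal, 0.0)
    inv_sign = np.where(neutral, 0.0, match)
    return vol_sign, inv_sign


def _templates(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    n_trials: int,
    t_rel: np.ndarray,
    amp_scale: tuple[float, float] = (1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Voluntary/involuntary time courses (n_trials, n_t) with onset jitter."""
    v, w = cfg.voluntary_bias, cfg.involuntary_bias
    v_onset = v.onset_ms + v.onset_jitter_sd_ms * rng.standard_normal(n_trials)
    w_onset = w.onset_ms + w.onset_jitter_sd_ms * rng.standard_normal(n_trials)
    tv = t_rel[None, :] - v_onset[:, None]
    vol = (
        amp_scale[0]
        * v.amplitude_pct
        * np.clip(tv / max(v.rise_ms, 1e-9), 0.0, 1.0)
    )
    if not v.sustained:
        vol = vol * np.exp(-np.maximum(tv - v.rise_ms, 0.0) / max(v.rise_ms, 1e-9))
    tw = t_rel[None, :] - w_onset[:, None]
    inv = (
        amp_scale[1]
        * w.amplitude_pct
        * np.clip(tw / max(w.rise_ms, 1e-9), 0.0, 1.0)
        * np.exp(-np.maximum(tw - w.rise_ms, 0.0) / max(w.decay_ms, 1e-9))
    )
    return vol, inv, v_onset, w_onset


def participant_amplitude_scales(
    cfg: GeneratorConfig, participant: int
) -> tuple[float, float]:
    """Mean-preserving lognormal individual differences in bias amplitudes.

    Participants differ in how strongly their gaze expresses the voluntary
    and (especially) the involuntary bias; this is what carries the
    across-participant competition correlation.
    """
    r = _rng(cfg.seed, participant, 5)
    z = r.standard_normal(2)
    cvs = (cfg.voluntary_bias.amplitude_cv, cfg.involuntary_bias.amplitude_cv)
    return tuple(
        float(np.exp(cv * zi - cv * cv / 2.0)) for cv, zi in zip(cvs, z)
    )


def _place_blinks(
    cfg: GeneratorConfig, rng: np.random.Generator, n_trials: int, n_t: int
) -> list[list[tuple[int, int]]]:
    bl = cfg.blink
    out: list[list[tuple[int, int]]] = []
    dur_s = n_t / cfg.sampling_rate_hz
    margin = int(bl.edge_margin_ms)
    for _ in range(n_trials):
        k = rng.poisson(bl.rate_per_s * dur_s)
        spans: list[tuple[int, int]] = []
        for _ in range(k):
            dur = int(rng.uniform(bl.duration_ms_min, bl.duration_ms_max))
            hi = n_t - dur - margin
            if hi <= margin:
                continue
            start = int(rng.integers(margin, hi))
            spans.append((start, start + dur - 1))
        out.append(spans)
    return out


def generate_participant_gaze(
    cfg: GeneratorConfig,
    trials: pd.DataFrame,
    participant: int,
    swap: np.ndarray | None = None,
) -> tuple[BinocularGaze, pd.DataFrame]:
    """Raw-unit binocular gaze for one participant's trials, plus gaze truth.

    ``swap`` marks trials on which the wrong (non-target) item was reported;
    with ``behavior.swap_inverts_voluntary`` the voluntary component follows
    the selected item on those trials, coupling gaze bias to performance.
    """
    rng = _rng(cfg.seed, participant, 2)
    geom = participant_geometry(cfg, participant)
    n_trials = len(trials)
    n_t = int(cfg.trial_end_ms) + 1
    time = np.arange(n_t, dtype=float)
    t_rel = time - cfg.cue_onset_ms
    fx = cfg.fixation_noise

    drift_x = _ou(rng, (n_trials, n_t), fx.reversion_rate, fx.diffusion)
    drift_y = _ou(rng, (n_trials, n_t), fx.reversion_rate, fx.diffusion)
    amp_scale = participant_amplitude_scales(cfg, participant)
    vol, inv, v_onset, w_onset = _templates(cfg, rng, n_trials, t_rel, amp_scale)
    vol_sign, inv_sign = _bias_signs(trials)
    if swap is not None and cfg.behavior.swap_inverts_voluntary:
        vol_sign = np.where(np.asarray(swap, bool), -vol_sign, vol_sign)
    scale = cfg.item_eccentricity_pct / 100.0
    x_true = drift_x + scale * (vol * vol_sign[:, None] + inv * inv_sign[:, None])
    y_true = drift_y

    # saccade-like excursions: smooth transient departures beyond the
    # fixation bound, in a random direction along the horizontal axis
    ex = cfg.excursion
    has_excursion = rng.random(n_trials) < ex.prob_per_trial
    for i in np.flatnonzero(has_excursion):
        dur = int(rng.uniform(ex.duration_ms_min, ex.duration_ms_max))
        lo = int(cfg.encoding_onset_ms)
        hi = int(cfg.probe_onset_ms) - dur
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        amp = rng.uniform(ex.amplitude_pct_min, ex.amplitude_pct_max)
        amp *= rng.choice([-1.0, 1.0])
        u = np.linspace(0.0, 1.0, dur)
        x_true[i, start : start + dur] += amp * 0.5 * (1 - np.cos(2 * np.pi * u))

    sd = fx.measurement_noise_sd_pct
    eyes = {}
    for eye in ("left", "right"):
        eyes[f"x_{eye}"] = geom.x_offset + geom.x_gain * (
            x_true + sd * rng.standard_normal((n_trials, n_t))
        )
        eyes[f"y_{eye}"] = geom.y_offset + geom.y_gain * (
            y_true + sd * rng.standard_normal((n_trials, n_t))
        )
        # pupil dynamics are out of scope: constant baseline, 0 marks blinks
        eyes[f"pupil_{eye}"] = np.full((n_trials, n_t), 1000.0)

    blink_spans = _place_blinks(cfg, rng, n_trials, n_t)
    for i, spans in enumerate(blink_spans):
        for s, e in spans:
            sl = slice(s, e + 1)
            for eye in ("left", "right"):
                eyes[f"pupil_{eye}"][i, sl] = 0.0
                eyes[f"x_{eye}"][i, sl] = 0.0  # rails off-screen in raw units
                eyes[f"y_{eye}"][i, sl] = 0.0

    gaze = BinocularGaze(
        participant=participant,
        trial_ids=trials["trial"].to_numpy().astype(int),
        time_ms=time,
        **eyes,
    )
    gtruth = pd.DataFrame(
        {
            "participant": participant,
            "trial": trials["trial"].to_numpy(),
            "voluntary_onset_ms": np.where(vol_sign != 0, v_onset, np.nan),
            "involuntary_onset_ms": np.where(inv_sign != 0, w_onset, np.nan),
            "voluntary_sign": vol_sign,
            "involuntary_sign": inv_sign,
            "has_excursion": has_excursion,
            "n_blinks": [len(s) for s in blink_spans],
        }
    )
    return gaze, gtruth


def generate_calibration(
    cfg: GeneratorConfig, participant: int | None = None
) -> pd.DataFrame:
    """Calibration-module sample table (7 positions × 3 visits per module).

    One module per three task blocks. Each visit lasts 1000–1500 ms; ground
    truth raw position is offset + gain × nominal %, plus fixational noise.
    """
    if participant is None:
        frames = [
            generate_calibration(cfg, p) for p in range(1, cfg.n_participants + 1)
        ]
        return pd.concat(frames, ignore_index=True)
    rng = _rng(cfg.seed, participant, 4)
    geom = participant_geometry(cfg, participant)
    g = cfg.calibration
    fx = cfg.fixation_noise
    sd = fx.measurement_noise_sd_pct
    n_modules = max(cfg.n_blocks // 3, 1)
    labels = list(CALIB_POSITIONS)
    cols: dict[str, list[np.ndarray]] = {
        c: []
        for c in (
            "module",
            "position",
            "visit",
            "time_ms",
            "x_left",
            "y_left",
            "x_right",
            "y_right",
            "pupil_left",
            "pupil_right",
        )
    }
    n_visits = 3 * len(labels)
    max_dur = int(g.visit_ms_max) + 1
    for module in range(1, n_modules + 1):
        order = labels * 3
        rng.shuffle(order)
        durs = rng.uniform(g.visit_ms_min, g.visit_ms_max, n_visits).astype(int)
        # one padded OU + noise block per module, sliced per visit
        dx = _ou(rng, (n_visits, max_dur), fx.reversion_rate, fx.diffusion)
        dy = _ou(rng, (n_visits, max_dur), fx.reversion_rate, fx.diffusion)
        noise = sd * rng.standard_normal((4, n_visits, max_dur))
        visit_of: dict[str, int] = {lab: 0 for lab in labels}
        for k, lab in enumerate(order):
            visit_of[lab] += 1
            dur = durs[k]
            nomx, nomy = CALIB_POSITIONS[lab]
            cols["module"].append(np.full(dur, module))
            cols["position"].append(np.full(dur, lab, dtype=object))
            cols["visit"].append(np.full(dur, visit_of[lab]))
            cols["time_ms"].append(np.arange(dur, dtype=float))
            for j, eye in enumerate(("left", "right")):
                cols[f"x_{eye}"].append(
                    geom.x_offset
                    + geom.x_gain * (nomx + dx[k, :dur] + noise[2 * j, k, :dur])
                )
                cols[f"y_{eye}"].append(
                    geom.y_offset
                    + geom.y_gain * (nomy + dy[k, :dur] + noise[2 * j + 1, k, :dur])
                )
                cols[f"pupil_{eye}"].append(np.full(dur, 1000.0))
    df = pd.DataFrame({c: np.concatenate(v) for c, v in cols.items()})
    df.insert(0, "participant", participant)
    return df


def generate_participant(
    cfg: GeneratorConfig, participant: int
) -> tuple[BinocularGaze, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(gaze, trials, calibration, truth) for a single participant."""
    trials = make_trials(cfg, participant)
    trials, behav_truth = simulate_behavior(cfg, trials, participant)
    gaze, gaze_truth = generate_participant_gaze(
        cfg, trials, participant, swap=behav_truth["swap"].to_numpy()
    )
    truth = behav_truth.merge(
        gaze_truth.drop(columns="participant"), on="trial"
    )
    calib = generate_calibration(cfg, participant)
    return gaze, trials[TRIAL_COLUMNS], calib, truth


def generate_experiment(cfg: GeneratorConfig) -> Experiment:
    """Generate the full experiment for all participants.

    For large configs prefer iterating :func:`generate_participant` and
    discarding raw gaze after preprocessing; this convenience function keeps
    everything in memory.
    """
    cfg.validate()
    gaze: dict[int, BinocularGaze] = {}
    trials, calib, truth = [], [], []
    for p in range(1, cfg.n_participants + 1):
        g, t, c, gt = generate_participant(cfg, p)
        gaze[p] = g
        trials.append(t)
        calib.append(c)
        truth.append(gt)
    return Experiment(
        gaze=gaze,
        trials=pd.concat(trials, ignore_index=True),
        calibration=pd.concat(calib, ignore_index=True),
        truth=pd.concat(truth, ignore_index=True),
    )


def write_experiment(exp: Experiment, outdir) -> None:
    """Write the three package tables + ground truth as tab-delimited text."""
    import os

    os.makedirs(outdir, exist_ok=True)
    gaze_frames = [g.to_frame() for g in exp.gaze.values()]
    pd.concat(gaze_frames, ignore_index=True).to_csv(
        os.path.join(outdir, "gaze.tsv"), sep="\t", index=False
    )
    exp.trials.to_csv(os.path.join(outdir, "trials.tsv"), sep="\t", index=False)
    exp.calibration.to_csv(
        os.path.join(outdir, "calibration.tsv"), sep="\t", index=False
    )
    exp.truth.to_csv(os.path.join(outdir, "ground_truth.tsv"), sep="\t", index=False)
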