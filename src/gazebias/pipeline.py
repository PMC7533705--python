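"""End-to-end orchestration: preprocess → calibrate → filter → towardness /
density → inference → behavior, from a single config, with a reproducible
manifest.

Participants are processed one at a time (raw gaze is discarded after
epoching) so the full 25 × 720-trial design fits comfortably in memory.
Neutral-cue trials, when present, are carried through the tables but ignored
by every analysis. Group analyses run on participants that pass the
mixture-model exclusion rule (anti-block correct-report weight ≥ 0.5).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    BehavioralSummary,
    circular_error,
    exclusion_flag,
    fit_report_mixture,
    remove_rt_outliers,
    two_by_two,
)
from .calibration import estimate_all, normalize_by_module
from .config import AnalysisConfig, RunConfig
from .containers import BinocularGaze, Epochs
from .inference import (
    ClusterResult,
    cluster_test,
    competition_correlations,
    jackknife_latency,
    median_split_towardness,
)
from .metrics import (
    GOAL_CODED,
    MATCH_CODED,
    ConditionCurves,
    DensityMap,
    assign_side,
    density_map,
    filter_fixation_trials,
    towardness,
)
from .preprocess import preprocess_participant
from .synth import generate_participant
from . import io as gio

logger = logging.getLogger(__name__)

#: gaze-analysis groupings: (name, trial selector, coding scheme)
GAZE_CONDITIONS = (
    ("null", lambda t: t["block_type"] == "null", MATCH_CODED),
    ("pro", lambda t: t["condition"] == "pro", GOAL_CODED),
    ("anti", lambda t: t["condition"] == "anti", GOAL_CODED),
)


@dataclass
class ParticipantResult:
    participant: int
    trials: pd.DataFrame  # with error_deg / rt_included columns
    retention: float
    n_invalid: int
    curves: dict[str, object]  # condition -> TowardnessTimecourse | None
    cond_epochs: dict[str, Epochs]
    cond_sides: dict[str, np.ndarray]
    density_counts: dict[tuple[str, str], tuple[np.ndarray, int]]
    mixture: object | None
    excluded: bool
    calibration_models: dict = field(default_factory=dict)


@dataclass
class StudyResult:
    analysis: AnalysisConfig
    participants: list[ParticipantResult]
    curves: dict[str, ConditionCurves]
    cluster_results: dict[str, ClusterResult]
    latency: object
    correlations: dict
    behavior: dict[str, BehavioralSummary]
    behavior_means: pd.DataFrame
    median_splits: dict[str, dict]
    density: dict[str, DensityMap]
    retention_mean: float = float("nan")
    retention_sd: float = float("nan")
    excluded_participants: list[int] = field(default_factory=list)
    mixture_correct_mean: float = float("nan")
    mixture_correct_sd: float = float("nan")


def analyze_participant(
    gaze: BinocularGaze,
    trials: pd.DataFrame,
    calib: pd.DataFrame,
    acfg: AnalysisConfig,
) -> ParticipantResult:
    """Single-participant pipeline up to towardness curves and behavior."""
    trials = trials.reset_index(drop=True)
    enc_rel = float((trials["encoding_onset_ms"] - trials["cue_onset_ms"]).iloc[0])
    probe_rel = float((trials["probe_onset_ms"] - trials["cue_onset_ms"]).iloc[0])
    w0, w1 = acfg.epoch_window_ms
    wide = (min(enc_rel, w0), max(probe_rel, w1))

    raw_epochs = preprocess_participant(
        gaze,
        trials,
        window_ms=wide,
        merge_gap_ms=acfg.blink_merge_gap_ms,
        pad_ms=acfg.blink_pad_ms,
        flank_ms=acfg.spline_flank_ms,
        anchor_bin_ms=acfg.spline_anchor_bin_ms,
        raw_bound=acfg.raw_gaze_bound,
    )
    models = estimate_all(calib, window_ms=acfg.calib_median_window_ms)
    norm = normalize_by_module(raw_epochs, trials, models)
    mask, retention = filter_fixation_trials(
        norm, bound_pct=acfg.fixation_bound_pct, span_ms=(enc_rel, probe_rel)
    )
    # analysis window slice
    sel = (norm.time_ms >= w0) & (norm.time_ms <= w1)
    epochs = Epochs(
        participant=norm.participant,
        trial_ids=norm.trial_ids,
        time_ms=norm.time_ms[sel],
        x=norm.x[:, sel],
        y=norm.y[:, sel],
        valid=norm.valid[:, sel],
        invalid_trials=set(norm.invalid_trials),
    )

    # behavior columns
    trials = trials.copy()
    trials["error_deg"] = circular_error(
        trials["report_ori"].to_numpy(), trials["target_ori"].to_numpy()
    )
    main = trials["condition"].isin(["pro", "anti", "match", "nonmatch"]).to_numpy()
    rt_inc = np.zeros(len(trials), bool)
    rt_inc[main] = remove_rt_outliers(
        trials.loc[main, "rt_ms"].to_numpy(), acfg.rt_z_bound, acfg.rt_max_iters
    )
    trials["rt_included"] = rt_inc
    incl = pd.Series(mask, index=trials.index)
    trials["gaze_included"] = incl

    curves: dict[str, object] = {}
    cond_epochs: dict[str, Epochs] = {}
    cond_sides: dict[str, np.ndarray] = {}
    density_counts: dict[tuple[str, str], tuple[np.ndarray, int]] = {}
    for name, selector, scheme in GAZE_CONDITIONS:
        in_cond = selector(trials).to_numpy() & (
            trials["condition"] != "neutral"
        ).to_numpy()
        sides_all = np.full(len(trials), "", dtype=object)
        ct = trials[in_cond]
        sides_all[in_cond] = assign_side(ct, scheme).to_numpy()
        # towardness on fixation-filtered trials
        use = in_cond & mask
        ep_c = epochs.subset(use)
        sides_c = sides_all[use]
        curves[name] = towardness(ep_c, sides_c, name, acfg.smoothing_sd_ms)
        cond_epochs[name] = ep_c
        cond_sides[name] = sides_c
        # density maps: no ±50% filter, but drop interpolation-invalid trials
        dens_use = in_cond & ~np.isin(
            trials["trial"].to_numpy(), sorted(epochs.invalid_trials)
        )
        for side in ("left", "right"):
            rows = dens_use & (sides_all == side)
            if rows.sum() == 0:
                continue
            m = density_map(
                epochs.subset(rows),
                window_ms=acfg.density_window_ms,
                bin_pct=acfg.density_bin_pct,
                smooth_sd_pct=0.0,
            )
            density_counts[(name, side)] = (
                m.values * m.n_samples,
                m.n_samples,
            )

    # mixture model on anti-block trials
    anti = trials[trials["condition"] == "anti"]
    mixture = None
    excluded = False
    if len(anti) >= 30:
        mixture = fit_report_mixture(
            anti["report_ori"].to_numpy(),
            anti["target_ori"].to_numpy(),
            anti["nontarget_ori"].to_numpy(),
            kappa_cap=acfg.mixture_kappa_cap,
            restarts=acfg.mixture_restarts,
            seed=acfg.seed + gaze.participant,
        )
        excluded = exclusion_flag(mixture)

    return ParticipantResult(
        participant=gaze.participant,
        trials=trials,
        retention=retention,
        n_invalid=len(epochs.invalid_trials),
        curves=curves,
        cond_epochs=cond_epochs,
        cond_sides=cond_sides,
        density_counts=density_counts,
        mixture=mixture,
        excluded=excluded,
        calibration_models={
            f"module_{m}": {
                "x_offset": mod.x_offset,
                "x_gain": mod.x_gain,
                "y_offset": mod.y_offset,
                "y_gain": mod.y_gain,
            }
            for (_, m), mod in sorted(models.items())
        },
    )


def _condition_means(
    results: list[ParticipantResult], col: str, rt_filtered: bool
) -> pd.DataFrame:
    rows = {}
    for r in results:
        t = r.trials
        use = t["condition"].isin(["pro", "anti", "match", "nonmatch"])
        if rt_filtered:
            use &= t["rt_included"]
        rows[r.participant] = t[use].groupby("condition")[col].mean()
    return pd.DataFrame(rows).T


def _spawn_seed(base: int, idx: int) -> int:
    return int(
        np.random.SeedSequence([int(base) & 0x7FFFFFFF, idx]).generate_state(1)[0]
        & 0x7FFFFFFF
    )


def analyze_study(
    results: list[ParticipantResult], acfg: AnalysisConfig
) -> StudyResult:
    """Group-level inference over per-participant results."""
    excluded = [r.participant for r in results if r.excluded]
    usable = [r for r in results if not r.excluded]
    if len(usable) < 2:
        raise ValueError("need at least 2 non-excluded participants")

    curves: dict[str, ConditionCurves] = {}
    for name, _, _ in GAZE_CONDITIONS:
        cc = None
        for r in usable:
            tc = r.curves.get(name)
            if tc is None:
                logger.info("participant %d missing condition %s", r.participant, name)
                continue
            if cc is None:
                cc = ConditionCurves(condition=name, time_ms=tc.time_ms)
            cc.add(tc)
        if cc is None:
            raise ValueError(f"no participants with condition {name}")
        curves[name] = cc

    time_ms = curves["pro"].time_ms
    cluster_results: dict[str, ClusterResult] = {}
    seed_i = 0
    for name in ("null", "pro", "anti"):
        cluster_results[f"{name}_vs_0"] = cluster_test(
            curves[name].stack(),
            time_ms,
            n_perm=acfg.n_permutations,
            seed=_spawn_seed(acfg.seed, seed_i),
            alpha=acfg.cluster_alpha,
        )
        seed_i += 1
    common = sorted(
        set(curves["pro"].participants) & set(curves["null"].participants)
    )
    pro_m = {p: c for p, c in zip(curves["pro"].participants, curves["pro"].curves)}
    null_m = {p: c for p, c in zip(curves["null"].participants, curves["null"].curves)}
    anti_m = {p: c for p, c in zip(curves["anti"].participants, curves["anti"].curves)}
    cluster_results["pro_vs_null"] = cluster_test(
        np.vstack([pro_m[p] for p in common]),
        time_ms,
        data_b=np.vstack([null_m[p] for p in common]),
        n_perm=acfg.n_permutations,
        seed=_spawn_seed(acfg.seed, seed_i),
        alpha=acfg.cluster_alpha,
    )
    seed_i += 1

    paired = sorted(set(pro_m) & set(anti_m) & set(null_m))
    pro_stack = np.vstack([pro_m[p] for p in paired])
    anti_stack = np.vstack([anti_m[p] for p in paired])
    null_stack = np.vstack([null_m[p] for p in paired])
    latency = jackknife_latency(
        pro_stack,
        anti_stack,
        time_ms,
        fraction=acfg.onset_fraction,
        window_ms=acfg.onset_window_ms,
        condition_a="pro",
        condition_b="anti",
    )
    correlations = competition_correlations(
        null_stack,
        pro_stack,
        anti_stack,
        time_ms,
        time_window_ms=acfg.corr_time_window_ms,
        participant_window_ms=acfg.corr_participant_window_ms,
    )

    behavior: dict[str, BehavioralSummary] = {}
    err_means = _condition_means(usable, "error_deg", rt_filtered=True)
    rt_means = _condition_means(usable, "rt_ms", rt_filtered=True)
    behavior["error"] = two_by_two(err_means, measure="reproduction error (deg)")
    behavior["rt"] = two_by_two(rt_means, measure="response time (ms)")
    mean_rows = []
    for meas, df in (("error_deg", err_means), ("rt_ms", rt_means)):
        d = df.reset_index(names="participant").melt(
            id_vars="participant", var_name="condition", value_name="value"
        )
        d.insert(1, "measure", meas)
        mean_rows.append(d)
    behavior_means = pd.concat(mean_rows, ignore_index=True)

    # median splits: gaze bias vs subsequent performance
    median_splits: dict[str, dict] = {}
    trials_all = pd.concat([r.trials for r in usable], ignore_index=True)
    for name, _, _ in GAZE_CONDITIONS:
        sel = (
            trials_all["gaze_included"]
            & trials_all["rt_included"]
            & (
                (trials_all["block_type"] == "null")
                if name == "null"
                else (trials_all["condition"] == name)
            )
        )
        cond_trials = trials_all[sel]
        ep_by_p = {r.participant: r.cond_epochs[name] for r in usable}
        sides_by_p = {
            r.participant: pd.Series(r.cond_sides[name]) for r in usable
        }
        for by in ("error", "rt"):
            try:
                median_splits[f"{name}_{by}"] = median_split_towardness(
                    cond_trials,
                    ep_by_p,
                    sides_by_p,
                    condition=name,
                    by=by,
                    smoothing_sd_ms=acfg.smoothing_sd_ms,
                    n_perm=acfg.n_permutations,
                    seed=_spawn_seed(acfg.seed, seed_i),
                )
            except ValueError as exc:
                logger.warning("median split %s/%s skipped: %s", name, by, exc)
            seed_i += 1

    # pooled density difference maps per condition
    density: dict[str, DensityMap] = {}
    from scipy.ndimage import gaussian_filter

    for name, _, _ in GAZE_CONDITIONS:
        maps = {}
        for side in ("left", "right"):
            counts, total = None, 0
            for r in usable:
                entry = r.density_counts.get((name, side))
                if entry is None:
                    continue
                c, n = entry
                counts = c if counts is None else counts + c
                total += n
            if counts is None or total == 0:
                break
            dens = counts / total
            if acfg.density_smooth_sd_pct > 0:
                dens = gaussian_filter(
                    dens,
                    sigma=acfg.density_smooth_sd_pct / acfg.density_bin_pct,
                    mode="constant",
                    truncate=4.0,
                )
            maps[side] = dens
        if len(maps) == 2:
            half = acfg.density_bin_pct / 2.0
            centers = np.arange(-100.0, 100.0 + 1e-9, acfg.density_bin_pct)
            density[name] = DensityMap(
                x_centers=centers,
                y_centers=centers,
                values=maps["left"] - maps["right"],
                signed=True,
            )

    retentions = np.array([r.retention for r in usable])
    correct = np.array(
        [r.mixture.w_target for r in usable if r.mixture is not None]
    )
    return StudyResult(
        analysis=acfg,
        participants=results,
        curves=curves,
        cluster_results=cluster_results,
        latency=latency,
        correlations=correlations,
        behavior=behavior,
        behavior_means=behavior_means,
        median_splits=median_splits,
        density=density,
        retention_mean=float(retentions.mean()),
        retention_sd=float(retentions.std(ddof=1)) if len(retentions) > 1 else 0.0,
        excluded_participants=excluded,
        mixture_correct_mean=float(correct.mean()) if len(correct) else float("nan"),
        mixture_correct_sd=float(correct.std(ddof=1)) if len(correct) > 1 else float("nan"),
    )


def iter_participants(cfg: RunConfig):
    """Yield (gaze, trials, calibration) per participant from config source."""
    if cfg.generator is not None:
        gen = cfg.generator
        for p in range(1, gen.n_participants + 1):
            gaze, trials, calib, _ = generate_participant(gen, p)
            yield gaze, trials, calib
    else:
        if not (cfg.gaze_path and cfg.trials_path and cfg.calibration_path):
            raise ValueError("either a generator config or all three table paths")
        gaze_all = gio.read_gaze(cfg.gaze_path)
        trials_all = gio.read_table(cfg.trials_path)
        calib_all = gio.read_table(cfg.calibration_path)
        for p in sorted(gaze_all):
            yield (
                gaze_all[p],
                trials_all[trials_all["participant"] == p],
                calib_all[calib_all["participant"] == p],
            )


def run_pipeline(cfg: RunConfig) -> StudyResult:
    """Execute the full pipeline and write all outputs to cfg.output_dir."""
    acfg = cfg.analysis
    results = []
    for gaze, trials, calib in iter_participants(cfg):
        logger.info("analyzing participant %d", gaze.participant)
        results.append(analyze_participant(gaze, trials, calib, acfg))
    study = analyze_study(results, acfg)
    write_report(cfg, study)
    return study


def write_report(cfg: RunConfig, study: StudyResult) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    acfg = study.analysis

    rows = []
    for name, cc in study.curves.items():
        for p, curve in zip(cc.participants, cc.curves):
            rows.append(
                pd.DataFrame(
                    {
                        "participant": p,
                        "condition": name,
                        "time_ms": cc.time_ms,
                        "towardness_pct": curve,
                    }
                )
            )
    gio.write_table(pd.concat(rows, ignore_index=True), out / "towardness.tsv")
    group = pd.concat(
        [
            pd.DataFrame(
                {
                    "condition": name,
                    "time_ms": cc.time_ms,
                    "towardness_pct": cc.group_mean(),
                }
            )
            for name, cc in study.curves.items()
        ],
        ignore_index=True,
    )
    gio.write_table(group, out / "group_towardness.tsv")
    gio.write_table(study.behavior_means, out / "behavior_means.tsv")
    for name, dm in study.density.items():
        gio.write_table(dm.to_frame(), out / f"density_diff_{name}.tsv")

    report = {
        "clusters": {k: v.to_dict() for k, v in study.cluster_results.items()},
        "latency": study.latency.to_dict(),
        "correlations": study.correlations,
        "behavior": {k: v.to_dict() for k, v in study.behavior.items()},
        "median_splits": {
            k: {
                "condition": v["condition"],
                "by": v["by"],
                "missing_participants": v["missing_participants"],
                "cluster": v["cluster"].to_dict(),
            }
            for k, v in study.median_splits.items()
        },
        "retention": {
            "mean": study.retention_mean,
            "sd": study.retention_sd,
            "per_participant": {
                r.participant: r.retention for r in study.participants
            },
        },
        "exclusions": {
            "excluded_participants": study.excluded_participants,
            "mixture_correct_mean": study.mixture_correct_mean,
            "mixture_correct_sd": study.mixture_correct_sd,
            "per_participant": {
                r.participant: (
                    r.mixture.to_dict() if r.mixture is not None else None
                )
                for r in study.participants
            },
        },
    }
    (out / "results.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "calibration_models.json").write_text(
        json.dumps(
            {
                str(r.participant): r.calibration_models
                for r in study.participants
            },
            indent=2,
            sort_keys=True,
        )
    )

    cfg_yaml = cfg.to_yaml()
    # hash the scientific config only: the output location is not part of it
    hashed = "\n".join(
        ln for ln in cfg_yaml.splitlines() if not ln.startswith("output_dir")
    )
    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(hashed.encode()).hexdigest(),
        "analysis_seed": acfg.seed,
        "generator_seed": cfg.generator.seed if cfg.generator else None,
        "n_permutations": acfg.n_permutations,
        "stage_counts": {
            "participants": len(study.participants),
            "excluded_participants": study.excluded_participants,
            "trials_per_participant": {
                r.participant: int(len(r.trials)) for r in study.participants
            },
            "invalid_trials_per_participant": {
                r.participant: r.n_invalid for r in study.participants
            },
            "gaze_retention_per_participant": {
                r.participant: r.retention for r in study.participants
            },
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(cfg_yaml)
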