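"""Configuration objects for the synthetic experiment generator and the analysis pipeline.

All tunables carry the study's values as defaults: two memory items at ±5.7°
visual angle (≡ ±100% in normalized gaze units), retrocue at 1 s after encoding
onset, probe 2 s after the cue, 15 superblocks × {pro, anti, null} × 16 trials
= 720 trials per participant, 1000-Hz binocular sampling.

Configs round-trip losslessly through YAML (`to_yaml` / `from_yaml`).
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class VoluntaryBias:
    """Goal-directed gaze-bias template: ramp to a sustained plateau.

    Times are ms relative to retrocue onset; amplitude in normalized % units
    (100% = item center at 5.7° eccentricity).
    """

    onset_ms: float = 320.0
    rise_ms: float = 400.0
    amplitude_pct: float = 4.0
    # between-participant amplitude variability (mean-preserving lognormal CV)
    amplitude_cv: float = 0.3
    sustained: bool = True
    onset_jitter_sd_ms: float = 30.0


@dataclass
class InvoluntaryBias:
    """Stimulus-driven (capture) template: ramp then exponential decay."""

    onset_ms: float = 250.0
    rise_ms: float = 350.0
    amplitude_pct: float = 2.0
    amplitude_cv: float = 0.5
    decay_ms: float = 400.0
    onset_jitter_sd_ms: float = 30.0


@dataclass
class FixationNoise:
    """Mean-reverting (Ornstein–Uhlenbeck) fixational drift + white measurement noise.

    ``reversion_rate`` is 1/ms (time constant 1/rate); ``diffusion`` is %²/ms.
    The stationary SD of the drift is sqrt(diffusion / (2 * reversion_rate)),
    4% with the defaults — fixational jitter of a few tenths of a degree.
    """

    reversion_rate: float = 0.02
    diffusion: float = 0.64
    measurement_noise_sd_pct: float = 0.5


@dataclass
class ExcursionModel:
    """Occasional large gaze shifts (saccade-like departures from fixation).

    A minority of trials contain one smooth transient excursion beyond the
    ±50% analysis bound; these are the trials the fixation filter removes,
    emulating the ~7% rejection rate of real recordings.
    """

    prob_per_trial: float = 0.07
    amplitude_pct_min: float = 55.0
    amplitude_pct_max: float = 120.0
    duration_ms_min: float = 200.0
    duration_ms_max: float = 400.0


@dataclass
class BlinkModel:
    """Poisson-placed blinks; pupil = 0 and gaze rails to an off-screen raw value."""

    rate_per_s: float = 0.15
    duration_ms_min: float = 100.0
    duration_ms_max: float = 300.0
    edge_margin_ms: float = 150.0


@dataclass
class BehaviorModel:
    """Continuous-report and RT model.

    Reports live in a 180°-periodic orientation space; errors are drawn as
    von Mises deviates on the doubled-angle (360°) circle and halved.
    Concentration is keyed by the cue-feature-match factor (the factor that
    drives report precision), with a multiplicative gain for informative cues.
    ``swap_prob`` is the per-condition probability of reporting the other
    (unprobed) item; ``guess_prob`` the probability of a uniform guess.
    RTs are shifted-lognormal with a lower median for informative cues and a
    small additional shift benefit when the cue's feature matches the probe.
    """

    kappa_match: float = 12.0
    kappa_nonmatch: float = 8.0
    kappa_informative_gain: float = 1.8
    swap_prob: dict[str, float] = field(
        default_factory=lambda: {
            "pro": 0.02,
            "anti": 0.08,
            "match": 0.02,
            "nonmatch": 0.04,
            "neutral": 0.03,
        }
    )
    guess_prob: float = 0.03
    # on swap trials the voluntary bias follows the item actually selected
    # (the non-target), linking trial-level gaze bias to report quality
    swap_inverts_voluntary: bool = True
    rt_shift_ms: float = 300.0
    rt_mu_informative: float = 5.967
    rt_mu_uninformative: float = 6.310
    rt_sigma: float = 0.35
    rt_match_benefit_ms: float = 32.0


@dataclass
class CalibrationGeometry:
    """Per-participant raw-unit map and the 7-point calibration layout.

    Raw units emulate screen pixels with down-positive y. Gains are raw units
    per normalized %; per-participant gains/offsets are jittered around these
    means so every participant needs its own calibration fit.
    """

    x_gain_mean: float = 2.6
    y_gain_mean: float = 2.6
    gain_jitter_sd: float = 0.2
    x_offset_mean: float = 840.0
    y_offset_mean: float = 525.0
    offset_jitter_sd: float = 30.0
    visit_ms_min: float = 1000.0
    visit_ms_max: float = 1500.0


@dataclass
class GeneratorConfig:
    """Full parameterization of one synthetic experiment."""

    n_participants: int = 25
    n_superblocks: int = 15
    trials_per_block: int = 16
    include_neutral: bool = False
    neutral_fraction: float = 0.25
    sampling_rate_hz: float = 1000.0
    item_eccentricity_pct: float = 100.0
    encoding_onset_ms: float = 0.0
    cue_onset_ms: float = 1000.0
    probe_onset_ms: float = 3000.0
    trial_end_ms: float = 3400.0
    voluntary_bias: VoluntaryBias = field(default_factory=VoluntaryBias)
    involuntary_bias: InvoluntaryBias = field(default_factory=InvoluntaryBias)
    fixation_noise: FixationNoise = field(default_factory=FixationNoise)
    excursion: ExcursionModel = field(default_factory=ExcursionModel)
    blink: BlinkModel = field(default_factory=BlinkModel)
    behavior: BehaviorModel = field(default_factory=BehaviorModel)
    calibration: CalibrationGeometry = field(default_factory=CalibrationGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (
            self.encoding_onset_ms < self.cue_onset_ms < self.probe_onset_ms
        ):
            raise ValueError(
                "trial events must be ordered encoding < cue < probe; got "
                f"{self.encoding_onset_ms}, {self.cue_onset_ms}, {self.probe_onset_ms}"
            )
        if self.trial_end_ms <= self.probe_onset_ms:
            raise ValueError("trial_end_ms must be after probe_onset_ms")
        for name in ("n_participants", "n_superblocks", "trials_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        fx = self.fixation_noise
        if fx.reversion_rate < 0 or fx.diffusion < 0 or fx.measurement_noise_sd_pct < 0:
            raise ValueError("fixation-noise rates/SDs must be nonnegative")
        if self.blink.rate_per_s < 0:
            raise ValueError("blink rate must be nonnegative")
        if not 0 <= self.excursion.prob_per_trial <= 1:
            raise ValueError("excursion prob_per_trial outside [0, 1]")
        if self.blink.duration_ms_min > self.blink.duration_ms_max:
            raise ValueError("blink duration range inverted")
        for cond, p in self.behavior.swap_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"swap_prob[{cond}] outside [0, 1]")
        if not 0 <= self.behavior.guess_prob <= 1:
            raise ValueError("guess_prob outside [0, 1]")

    @property
    def n_blocks(self) -> int:
        return 3 * self.n_superblocks

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorConfig":
        d = dict(d)
        for key, sub in (
            ("voluntary_bias", VoluntaryBias),
            ("involuntary_bias", InvoluntaryBias),
            ("fixation_noise", FixationNoise),
            ("excursion", ExcursionModel),
            ("blink", BlinkModel),
            ("behavior", BehaviorModel),
            ("calibration", CalibrationGeometry),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(io.StringIO(text)))


@dataclass
class AnalysisConfig:
    """Every analysis tunable, with the study's value as default."""

    epoch_window_ms: tuple[float, float] = (-200.0, 2000.0)
    blink_merge_gap_ms: float = 50.0
    blink_pad_ms: float = 100.0
    spline_flank_ms: float = 200.0
    spline_anchor_bin_ms: float = 20.0
    raw_gaze_bound: float | None = None
    fixation_bound_pct: float = 50.0
    smoothing_sd_ms: float = 25.0
    density_window_ms: tuple[float, float] = (400.0, 1000.0)
    density_bin_pct: float = 1.0
    density_smooth_sd_pct: float = 10.0
    calib_median_window_ms: tuple[float, float] = (500.0, 1000.0)
    n_permutations: int = 10_000
    cluster_alpha: float = 0.05
    onset_fraction: float = 0.1
    onset_window_ms: tuple[float, float] = (0.0, 2000.0)
    corr_time_window_ms: tuple[float, float] = (0.0, 2000.0)
    corr_participant_window_ms: tuple[float, float] = (400.0, 800.0)
    rt_z_bound: float = 4.0
    rt_max_iters: int = 3
    mixture_kappa_cap: float = 500.0
    mixture_restarts: int = 10
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        d = dict(d)
        for k in (
            "epoch_window_ms",
            "density_window_ms",
            "calib_median_window_ms",
            "onset_window_ms",
            "corr_time_window_ms",
            "corr_participant_window_ms",
        ):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class RunConfig:
    """Top-level pipeline run: either generate synthetic data or load tables."""

    generator: GeneratorConfig | None = None
    gaze_path: str | None = None
    trials_path: str | None = None
    calibration_path: str | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "gazebias_out"

    def to_yaml(self) -> str:
        d: dict[str, Any] = {
            "generator": self.generator.to_dict() if self.generator else None,
            "gaze_path": self.gaze_path,
            "trials_path": self.trials_path,
            "calibration_path": self.calibration_path,
            "analysis": self.analysis.to_dict(),
            "output_dir": self.output_dir,
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(io.StringIO(text))
        gen = d.get("generator")
        return cls(
            generator=GeneratorConfig.from_dict(gen) if gen else None,
            gaze_path=d.get("gaze_path"),
            trials_path=d.get("trials_path"),
            calibration_path=d.get("calibration_path"),
            analysis=AnalysisConfig.from_dict(d.get("analysis", {})),
            output_dir=d.get("output_dir", "gazebias_out"),
        )
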