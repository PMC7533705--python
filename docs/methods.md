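# Methods

This note documents the models, estimators, and numerical choices behind
`gazebias`, and what its synthetic-data validation does and does not
establish about real recordings.

## The experimental design being analyzed

Participants hold two lateralized items (±5.7° visual angle ≡ ±100% in
normalized gaze units) in visual working memory and reproduce one item's
feature on a 180°-periodic dial after a delay. A retrocue — a transient
feature change of the fixation mark 1 s after encoding — is informative in
*pro* blocks (cue feature matches the to-be-probed item) and *anti* blocks
(cue feature matches the other item; the non-matching item will be probed),
and uninformative in *null* blocks, where trials are labelled *match* /
*nonmatch* post hoc by whether the cue feature happened to match the probed
item. The probe follows 2 s after the cue. This 2×2 crossing of cue
informativeness × cue-feature match separates voluntary (goal-directed)
from involuntary (stimulus-driven) selection of memory content. The package
analyzes the two behavioral signatures of that separation (reproduction
error, response time) and its oculomotor signature: a small directional
bias of fixational gaze toward the memorized location of the selected item.

## Gaze pipeline

1. **Blink handling.** Blinks are detected as maximal runs where either
   eye's pupil signal is ≤ 0 (or gaze exceeds an optional raw-range bound);
   runs closer than 50 ms are merged. All four gaze channels are replaced
   inside ±100 ms around each blink by a cubic spline (not-a-knot) fit
   through up to 200 ms of clean flanking data per side. Flank samples are
   averaged into 20-ms bins before the fit: an interpolating cubic through
   every raw sample inherits the sample-to-sample measurement noise in its
   edge derivatives and can swing by tens of percent across a 300-ms gap,
   whereas bin means bound that amplification while remaining exact for
   constant and linear signals. Blinks abutting a trial edge leave no
   anchor data; such trials are flagged invalid rather than extrapolated.
2. **Binocular averaging.** Cyclopean gaze is the mean of the available
   eyes, with monocular fallback when one eye is missing at a sample.
3. **Calibration.** Interleaved 7-point calibration modules (3 visits per
   position, 1–1.5 s each) are summarized by per-position medians over
   500–1,000 ms after point onset. The affine raw→% map uses the
   middle-row eccentric points for the horizontal gain ((right − left)/200)
   and the top-vs-bottom row means for the vertical gain; the center point
   gives the offsets. Corner points sit at (±100, ±100) in normalized
   units so both gains are exactly identifiable from the layout. Each task
   block is normalized with the nearest preceding module (first three
   blocks use the first module), tracking slow drift without lookahead.
4. **Epoching and filtering.** Epochs are cut on a shared axis relative to
   retrocue onset ([−200, 2000] ms for analysis) with no baseline
   correction — the left/right condition subtraction in towardness removes
   static offsets. The fixation filter keeps trials whose normalized gaze
   stayed within ±50% on *both* axes throughout encoding → probe
   (conservative reading of "throughout the trial"; the span and bound are
   configurable).
5. **Towardness.** Per participant and condition: average the per-trial
   horizontal traces within each coded side, smooth each side's average
   with a unit-mass Gaussian (SD 25 ms, truncated at ±4 SD,
   reflect-padded), then T(t) = (right-coded − left-coded)/2. Side coding
   is by the cue-feature-matching item in null blocks and by the
   to-be-probed item in pro/anti blocks. Smoothing before subtraction
   matches the stated order of the original procedure; by linearity the
   order does not change the estimate.
6. **Density maps.** Gaze samples from 400–1,000 ms post-cue are pooled
   across time and trials (no ±50% filter), binned at 1% over [−100, 100]²,
   divided by the total sample count (out-of-range samples count toward
   the total), smoothed with a 10%-SD 2-D Gaussian, and differenced between
   left- and right-cued trials after per-map smoothing.

## Inference

* **Cluster-based permutation test.** Sample-wise one-sample t values
  (on curves, or on paired differences), cluster-forming threshold at the
  two-tailed t critical value (α = 0.05, df n−1), clusters are maximal
  same-sign supra-threshold runs scored by summed t (maxsum). The null
  distribution is the maximum |cluster mass| over random participant
  sign flips; cluster p = (1 + #{null ≥ |mass|})/(n_perm + 1), with a
  10⁻⁹ relative tie tolerance so sign patterns that reproduce the observed
  mass (e.g., the identity flip) count as exceedances despite
  floating-point path differences. Zero-variance samples get t = 0
  (logged). Defaults: 10,000 permutations, recorded seed. The threshold
  and tail policy are config-exposed because common toolbox defaults for
  per-tail α handling are ambiguous; this package controls the two-sided
  family at 0.05 via the max-|mass| null.
* **Fractional-peak onset latency.** Onset = first time the group curve
  reaches 10% of its in-window ([0, 2000] ms) peak, linearly interpolated
  between the straddling 1-ms samples (removes grid quantization from the
  jackknife variance). A non-positive peak leaves the latency undefined.
* **Jackknife latency differences.** Leave-one-out grand-average latencies
  d_i, SE = sqrt((n−1)/n · Σ(d_i − d̄)²) — the (n−1)/n factor undoes the
  variance shrinkage of subsample statistics, and for a linear statistic
  this SE equals the classical SEM exactly (verified numerically). t =
  difference/SE with df n−1. Undefined leave-one-out latencies are dropped
  and counted; SE = 0 with a nonzero difference is flagged degenerate
  rather than reported as an ordinary t.
* **Competition correlations.** Series A = 2 × null-block towardness (the
  match-vs-nonmatch difference is exactly twice the match-coded
  towardness); series B = pro − anti towardness. Pearson r across time
  (group means, 0–2000 ms) and across participants (400–800-ms window
  means).
* **Median split.** Per participant × condition, trials strictly below the
  participant's median error (or RT) form the "good" half (deterministic
  tie rule; all-equal measures leave an empty good half and flag the
  participant). Halves are compared with the paired cluster test;
  participants need ≥ 2 trials per half per side.

## Behavior

Reproduction error is the minimal angular distance in the 180°-periodic
space (0–90°). RT outliers are removed per participant by iterating
|z| > 4 trimming at most three times. The 2×2 decomposition computes
per-participant contrasts — voluntary benefit = mean(match, nonmatch) −
mean(pro, anti); involuntary benefit = mean(anti, nonmatch) − mean(pro,
match); interaction = (pro − anti) − (match − nonmatch) — each tested as a
one-sample t, reported with F = t² (equal to the repeated-measures ANOVA F
on the same data, cross-checked against an independent sums-of-squares
implementation), Cohen's d = mean/SD, and partial η² = t²/(t² + n − 1).
Benefits are signed so positive = better performance.

The swap mixture doubles errors onto the 360° circle and fits, by EM, a
three-component mixture: von Mises at the target, von Mises at the
non-target's doubled offset with shared concentration κ (a shared κ keeps
the swap model identifiable), and a uniform guess component. κ is updated
by exactly inverting the mean-resultant equation A1(κ) = R (Brent root
find on I₁/I₀, capped at 500 for degenerate data), which keeps the EM
log-likelihood non-decreasing. Ten restarts from jittered moment-based
starts, tolerance 10⁻⁶, ≤ 500 iterations; the best likelihood wins.
Participants whose anti-block target weight falls below 0.5 are flagged
for exclusion and omitted from group analyses.

## The synthetic-data generator

The generator emulates the full design: per participant, 15 superblocks ×
{pro, anti, null} blocks (random order) × 16 trials = 720 trials, with
left/right, match/nonmatch, and item-color assignments balanced and
randomized as in the task; calibration modules after every three blocks.

Horizontal gaze is an additive model in normalized % units:

    x(t) = OU(t) + voluntary(t)·goal_sign + involuntary(t)·match_sign + ε

* **Fixational noise**: a discretized mean-reverting (Ornstein–Uhlenbeck)
  process (reversion 0.02 /ms, i.e. a 50-ms time constant; diffusion
  0.64 %²/ms → stationary SD ≈ 4%, a few tenths of a degree of fixational
  jitter) plus white measurement noise (SD 0.5%) independently per eye.
* **Voluntary component**: ramp to a sustained plateau (onset 320 ms after
  the cue, rise 400 ms, amplitude 4%), present in pro and anti blocks,
  signed toward the goal item. On swap trials it follows the item actually
  selected (the non-target), which links trial-level gaze bias to report
  quality and gives the median-split analysis a real effect to find.
* **Involuntary component**: ramp then exponential decay (onset 250 ms,
  rise 350 ms, amplitude 2%, decay constant 400 ms), present whenever the
  cue carries an item feature, signed toward the feature-matching item.
  In pro trials the components add; in anti trials they oppose; null
  trials carry only the involuntary component — the additive-competition
  structure under study.
* **Individual differences**: per-participant amplitude multipliers,
  mean-preserving lognormal with CV 0.3 (voluntary) and 0.5 (involuntary).
  Participants genuinely differ in how strongly gaze expresses each bias,
  and this heterogeneity is what carries the across-participant
  competition correlation (stronger capture in null blocks ↔ larger
  pro−anti difference); without it that correlation is noise around zero.
* Per-trial Gaussian onset jitter (SD 30 ms) on both components. The
  template timing constants were set so that the *measured*
  fractional-peak onsets of the resulting group curves (which sit earlier
  than the nominal template onsets, because the involuntary ramp
  contributes to the pro curve and jitter+smoothing advance the crossing)
  fall at ≈ 318 ms (pro) and ≈ 560 ms (anti) — the scale of the reported
  latencies — with a transient null-block bias fading by ~1.2 s.
* **Excursions**: 7% of trials contain one smooth saccade-like departure
  beyond ±50% (amplitude 55–120%, 200–400 ms), emulating the ~7% of real
  trials the fixation filter removes.
* **Blinks**: Poisson-placed (0.15 /s, 100–300 ms), both pupils set to 0
  and gaze railed off-screen; kept ≥150 ms from trial edges so the
  generator itself never produces uninterpolatable trials.
* **Behavior**: reports are von Mises draws on the doubled-angle circle
  (κ = 12 for feature-matching cues, 8 for non-matching, ×1.8 for
  informative cues — yielding error benefits of ≈ 2.9° for the match
  factor and ≈ 1.2° for informativeness), with condition-dependent swap
  probabilities (anti 8%, nonmatch 4%, else 2%) and a 3% uniform guess
  rate (anti-block correct-report weight ≈ 0.886). RTs are
  shifted-lognormal with an informativeness benefit of ≈ 170 ms and a
  feature-match benefit of 32 ms.
* **Calibration**: per-participant gains (≈ 2.6 raw units/%) and offsets
  are jittered so every participant genuinely needs its own fit.

Everything is reproducible bit-exactly from (config, seed); per-participant
streams are derived through seed sequences so participants can be generated
independently.

**What the generator does not emulate** — saccade main-sequence dynamics,
microsaccades, pupil-size dynamics beyond the blink marker, drift in
calibration gains within a session, serial-order and history effects, and
any RT–gaze trial-level coupling. Passing the validation suite therefore
shows that the estimators recover the structure of this model family at
realistic noise levels, not that real recordings satisfy that model.

## Validation problem sizes

The Monte-Carlo validation studies run the full generator → preprocess →
calibrate → filter → towardness chain:

* **Type-I calibration**: 500 replicate null studies (both amplitudes 0),
  25 participants × 12 trials, 1,000 permutations each. Trials per
  participant only scale the curve noise; the calibration of the
  across-participant t statistics does not depend on it, so the smallest
  balanced design is used.
* **Onset recovery**: 100 replicate studies, 25 participants × 240 trials.
  At 240 trials the pre-onset noise of the group anti curve sits ≈ 4 SD
  below the 10%-of-peak threshold, making spurious early crossings rare;
  smaller designs (≤ 144 trials) were measurably unreliable for the anti
  onset and are not used.
* `scripts/acceptance.py` reports the same quantities from 200 (type-I)
  and 50 (recovery) replicates alongside a full-design 25 × 720 showcase
  study analyzed with 10,000 permutations.

## Known limitations

* The ±50% fixation filter's exact temporal span and channel set in the
  original procedure are not documented; encoding→probe on both axes is a
  conservative, configurable choice.
* "Default" cluster settings of legacy toolboxes are ambiguous about
  per-tail α; the two-sided max-|mass| policy here is the cleanest
  FWER-controlling reading, and the threshold is configurable.
* The mixture model assumes a shared κ and independent trials; EM can hit
  the κ cap on (near-)noiseless data, which is reported rather than
  hidden.
* Printed effect-size conventions for η² differ across the literature;
  this package reports standard partial η² and Cohen's d only.
* EyeLink ASC/EDF ingestion is out of scope; external converters must
  produce the documented tables (`gazebias.io`).
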