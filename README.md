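# gazebias

Analysis toolkit for **gaze-bias (towardness) studies of attentional
selection in visual working memory** with pro-, anti-, and null-retrocues —
for cognitive-neuroscience labs running continuous-report memory tasks with
high-rate eye tracking, and for anyone who wants the full chain from raw
binocular samples to publication statistics as tested, scriptable code.

In these experiments participants memorize two lateralized items (±5.7°
visual angle ≡ ±100% in normalized gaze units) and reproduce one item's
feature after a delay. A retrocue during the delay either predicts the
probed item via a matching feature (*pro*), predicts the *other* item
(*anti*), or is uninformative (*null*, labelled match/nonmatch post hoc).
Crossing cue informativeness with cue-feature match separates voluntary
(goal-directed) from involuntary (stimulus-driven) selection of memory
content, and a small directional bias of fixational gaze tracks which item
is being selected, sample by sample.

The package implements:

* **Preprocessing** — blink detection, ±100-ms cubic-spline interpolation,
  binocular averaging, cue-locked epoching (`gazebias.preprocess`).
* **Calibration** — per-participant affine raw→% maps from interleaved
  7-point calibration modules, applied per block (`gazebias.calibration`).
* **Gaze metrics** — the towardness statistic
  T(t) = (x̄_right-coded(t) − x̄_left-coded(t))/2 on 25-ms-smoothed
  trial averages, the ±50% fixation-trial filter, and 2-D gaze-density
  difference maps (1% bins, 10% smoothing) (`gazebias.metrics`).
* **Inference** — cluster-based sign-flip permutation tests (maxsum
  statistic, max-|mass| null, 10,000 permutations), jackknife
  10%-of-peak onset latencies with SE = √((n−1)/n · Σ(dᵢ−d̄)²),
  competition correlations (pro−anti vs. 2×null towardness), and
  median-split linkage of gaze bias to trial-level performance
  (`gazebias.inference`).
* **Behavior** — circular reproduction errors in the 180° space, iterative
  |z|>4 RT trimming, the 2×2 voluntary/involuntary contrast decomposition,
  and an EM-fitted von Mises swap mixture (target/non-target/uniform) used
  for participant exclusion (`gazebias.behavior`).
* **Synthetic experiments** — a generator that emulates the complete
  design (25 participants × 720 trials, fixational Ornstein–Uhlenbeck
  noise, ramping voluntary and transient involuntary bias templates,
  blinks, excursions, swap/guess reports, RT effects), so every stage is
  verifiable against ground truth without any download
  (`gazebias.synth`, `gazebias.simulate`).

## Worked example

```python
from gazebias import GeneratorConfig, AnalysisConfig
from gazebias.synth import generate_participant
from gazebias.pipeline import analyze_participant, analyze_study

cfg = GeneratorConfig(n_participants=10, n_superblocks=5, seed=7)
acfg = AnalysisConfig(n_permutations=1000, seed=1)
results = [analyze_participant(*generate_participant(cfg, p)[:3], acfg)
           for p in range(1, 11)]
study = analyze_study(results, acfg)
print(f"retention {100*study.retention_mean:.1f}%")
for name, res in study.cluster_results.items():
    print(name, "min cluster p:", f"{res.min_p():.4g}",
          f"({len(res.significant)} significant)")
lat = study.latency
print(f"onsets pro {lat.onset_a_ms:.0f} ms, anti {lat.onset_b_ms:.0f} ms, "
      f"jackknife t({lat.df}) = {lat.t:.2f}")
print(f"r_time = {study.correlations['r_time']:.3f}")
b = study.behavior
print(f"RT benefits: voluntary {b['rt'].voluntary_benefit.mean():.0f} ms, "
      f"involuntary {b['rt'].involuntary_benefit.mean():.0f} ms")
print(f"error benefits: voluntary {b['error'].voluntary_benefit.mean():.1f} deg, "
      f"involuntary {b['error'].involuntary_benefit.mean():.1f} deg")
```

prints (exactly, for these seeds):

```
retention 91.5%
null_vs_0 min cluster p: 0.004995 (2 significant)
pro_vs_0 min cluster p: 0.001998 (1 significant)
anti_vs_0 min cluster p: 0.001998 (1 significant)
pro_vs_null min cluster p: 0.003996 (1 significant)
onsets pro 309 ms, anti 570 ms, jackknife t(9) = 5.91
r_time = 0.954
RT benefits: voluntary 162 ms, involuntary 33 ms
error benefits: voluntary 1.6 deg, involuntary 4.1 deg
```

Reading: ~92% of trials survive the ±50% fixation filter; gaze is biased
toward the cued item's memorized location in every condition (all three
one-sample cluster tests significant, more strongly for pro than null
cues); the goal-directed bias emerges ~260 ms later after anti-cues than
after pro-cues (jackknife t(9) = 5.91) because the involuntary capture by
the cue-matching item must first be overcome; the pro−anti towardness
difference tracks twice the null-block capture bias across time (r ≈ 0.95)
— the additive-competition signature; and behaviorally, informative cues
mostly speed responses (162 vs. 33 ms) while feature-matching cues mostly
improve precision (4.1° vs. 1.6°) — the voluntary/involuntary dissociation
the 2×2 design exists to measure.

The same pipeline runs from the command line on generated or converted
data:

```bash
gazebias generate --seed 7 --out tables/
gazebias validate --gaze tables/gaze.tsv --trials tables/trials.tsv \
    --calibration tables/calibration.tsv
gazebias analyze --config run.yaml --out out/
gazebias report --out out/
```

All inputs and outputs are tab-separated text tables plus JSON reports;
the column contracts (for converters from eye-tracker exports) are
documented in `gazebias.io` and `gazebias.containers`.

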