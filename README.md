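# spheregaze

Spherical gaze analysis for 360° VR viewing experiments: how do the eyes,
head, torso — and the chair you sit on — share the work of looking around?

When someone explores an immersive panorama, the eye tracker reports eye
direction *in the head*, the headset reports head orientation, and body
trackers report torso and chair yaw, all at different rates.  `spheregaze`
fuses these streams into positions on the unit view-sphere (longitude
λ ∈ [−180°, 180°), latitude φ ∈ [−90°, 90°]), finds fixations and saccades,
and quantifies how posture (sitting in a fixed chair, sitting in a swivel
chair, or standing) changes visual exploration and effector coordination.
It is written for vision scientists analyzing eye/head/body tracking from
VR experiments, and ships a synthetic generator of posture-conditioned
recordings so every analysis stage is testable without access to raw data.

## What it computes

* **Gaze integration** — eyes-in-space = head quaternion ⊗ eye-in-head
  vector; all distances are orthodromic (great-circle) angles.
* **Fixations & saccades** — a spherical dispersion-threshold (I-DT)
  detector: a fixation is a maximal window whose largest pairwise geodesic
  extent stays ≤ 3° and that lasts ≥ 80 ms; saccades connect successive
  centroids, gaps > 300 ms are discarded.
* **Exploration** — total gaze travel ∑ saccade amplitudes, and scene
  coverage as the union of 3° spherical caps around fixation centroids (a
  single cap covers 50·(1−cos θ) = 0.06852% of the sphere; overlap is
  resolved on an equal-area Fibonacci grid).
* **Spatial distributions** — longitude/latitude spreads, equator biases,
  heatmaps and mode structure for every frame in the chain: eyes-in-space,
  head, torso, torso-relative-chair, head-relative-torso, eyes-in-head.
* **Coordination** — eyes-in-head eccentricity time-locked to saccade
  starts (the head catches up to the eyes during fixations), and the
  latency between head and torso rotation onsets.
* **Group statistics** — repeated-measures ANOVA with Mauchly-gated
  Greenhouse–Geisser correction and generalized η², Bonferroni post-hocs,
  one-sample bias tests with Cohen's d.

See `docs/methods.md` for the models, conventions, and the generator's
calibration.

## Worked example

```python
import numpy as np
from spheregaze import synth, pipeline

cfg = synth.GeneratorConfig(n_subjects=3, trials_per_posture=5, seed=42)
trials = synth.generate_experiment(cfg)

by_posture = {}
for trial in trials:
    products = pipeline.process_trial(trial, with_coverage=True,
                                      coverage_resolution=200_000)
    by_posture.setdefault(trial.posture, []).append(products)

table = pipeline.trial_metrics_table([p for ps in by_posture.values() for p in ps])
print(table.groupby("posture")[["n_fixations", "mean_fix_dur_ms", "coverage"]].mean().round(2))

recovery = pipeline.condition_recovery(by_posture)
print(recovery[["gaze_sd_lon", "torso_sd_lon", "ecc_min", "delay_ms"]].round(1))
```

prints

```
         n_fixations  mean_fix_dur_ms  coverage
posture
sit            46.47           203.87      2.26
stand          45.60           202.72      2.28
swivel         45.13           206.41      2.22

         gaze_sd_lon  torso_sd_lon  ecc_min  delay_ms
posture
sit             56.5          10.4     16.2      55.3
swivel          82.6          49.0     17.6      40.4
stand           91.3          60.5     17.2      31.3
```

Reading it: each 10-second trial contains ~45 fixations of ~200 ms covering
~2.2% of the sphere.  Gaze and torso longitude spreads grow from sit to
swivel to stand (freedom to rotate widens exploration), the eyes-in-head
eccentricity bottoms out near 16–18° just before each saccade (the head
never quite catches the eyes), and torso rotation onsets trail head onsets
by ~55 ms seated but only ~31 ms standing.  At this toy scale (3 subjects ×
5 trials) the per-condition numbers are noisy; the test suite runs the full
27-subject × 30-trial design, where they recover the generator's configured
condition parameters to within a few percent.

The same pipeline runs from the shell:

```bash
spheregaze synth --subjects 27 --trials 30 --seed 1 --out store/
spheregaze events store/ --dispersion 3 --min-dur 80
spheregaze explore store/ --theta 3 --grid 500000
spheregaze dist store/ --frame eyes_in_space --heatmap
spheregaze coord store/ --window -400:200 --bin 4
spheregaze stats exploration.csv --dv coverage --within posture,stimulus_type
```

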