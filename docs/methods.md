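# Methods

## The analysis problem

A participant stands (or sits) at the center of a virtual sphere onto which
a 360° panorama is projected, and freely explores it for 10 s.  Three
orientation streams are recorded: eye-in-head direction vectors at a nominal
250 Hz, and head orientation quaternions plus torso (and, for a swivel
chair, chair) yaw at a nominal 90 Hz.  The analyses express everything on
the *view-sphere* in longitude λ ∈ [−180°, 180°) and latitude φ ∈ [−90°,
90°], with the trial-start direction at (0, 0).  Gaze ("eyes-in-space") is
the eye-in-head vector rotated by the head quaternion; all distances are
orthodromic (great-circle) angles, never distances on the equirectangular
map, which is badly distorted toward the poles.

The pipeline: synchronize the two streams onto the eye timebase (slerp for
quaternions, linear interpolation with ±180° unwrapping for yaws), detect
fixations with a dispersion-threshold algorithm, derive saccades between
successive fixations, and compute (i) exploration statistics — total gaze
travel ∑ saccade amplitudes and the percentage of the sphere covered by the
union of 3° caps around fixation centroids, (ii) longitude/latitude
distributions of every link in the effector chain (eyes-in-space, head,
torso, torso-relative-chair, head-relative-torso, eyes-in-head), and (iii)
temporal coordination — eyes-in-head eccentricity time-locked to saccade
onsets, and the latency from head to torso rotation onsets.  Group
inference uses subject-averaged cells in repeated-measures ANOVAs with
Mauchly-gated Greenhouse–Geisser correction, generalized η², Bonferroni
post-hocs, and one-sample t tests with Cohen's d = mean/sd.

## Fixation detection on the sphere

I-DT is defined planarly in the classic literature; here the dispersion of
a candidate window is the **maximum pairwise orthodromic distance** among
its samples, which is rotation-invariant and pole-safe.  Detection is the
classic greedy scheduling: the window starts at the earliest unconsumed
sample, must span the minimum duration (default 80 ms), grows while
dispersion ≤ threshold (default 3°), and restarts after an emitted window
(or slides by one sample when the minimal window already violates the
threshold).  The dispersion is maintained incrementally (each appended
sample is compared against the whole window), which is exact at every
step.  Centroids are renormalized vector means — immune to longitude
wraparound.  Saccades connect successive centroids; inter-fixation gaps
longer than 300 ms are discarded.  Samples flagged invalid split windows;
nothing is interpolated across them.

## Coverage

Explored area is the union of spherical caps of radius θ = 3° (the
dispersion radius) around all fixation centroids, as a percentage of 4π.
A single cap covers 50·(1−cos θ) = 0.06852% at θ = 3°; overlap between
neighboring fixations makes the union sub-additive.  The union is
evaluated on a Fibonacci-lattice grid (default 500 000 cells, each
≈ 0.0002% of the sphere, equal-area by construction): a cell is covered
when its center is within θ of any centroid, found with a KD-tree ball
query on chord distance.  At default resolution the single-cap estimate is
within 0.5% relative error of the closed form, and the union agrees with a
10⁶-point Monte-Carlo estimate within sampling error (tested on random
sets).

## Coordination analyses

*Eccentricity.*  Eyes-in-head eccentricity is the angle between the eye
direction and the head-forward axis.  Segments of the eccentricity series
in a [−400, +200] ms window around every saccade start (4 ms bins,
matching the 250 Hz timebase) are averaged across events; the reported
minimum is the minimum of the event-averaged curve at or before offset
zero.  The confidence band is the between-event 95% CI of the mean.
Event-level pooling across trials within a condition is used for
condition comparisons.

*Rotation onsets.*  Neither stream has a ground-truth movement marker, so
onsets are detected from the smoothed angular speed (50 ms boxcar on the
unwrapped yaw derivative): an onset opens at an upward crossing of 10°/s
and is kept when the movement accumulates ≥ 5° before the speed falls back
below 5°/s (hysteresis against double triggers).  A centered boxcar reacts
half a window early, so reported times are shifted by +25 ms; the shift is
common to head and torso and cancels in their difference.  Each torso
onset is paired with the nearest preceding head onset within 500 ms, each
head onset used at most once; the condition delay is the event mean of the
signed differences.

## Group statistics

pingouin supplies the repeated-measures ANOVA engine; this package pins
the policy: Greenhouse–Geisser df-correction is applied to an effect only
when Mauchly's test rejects sphericity at α = .05 (for interactions, when
the estimated ε < 1), both raw and corrected p are reported, effect sizes
are generalized η² under the all-factors-manipulated convention, sample
SDs use ddof = 1 at the subject level, and all tests are two-sided.

## The synthetic generator

No raw recordings are distributed, so a generator emulates the study's
structure: 27 subjects × 3 postures × 30 trials of 10 s, eye stream at
250 Hz, body stream at 90 Hz, alternating indoor/outdoor labels.  Each
posture profile carries the condition parameters the analyses should
recover: gaze longitude/latitude spreads, torso spread (and
torso-relative-chair spread for swivel), head and eyes-in-head latitude
biases, the eccentricity minimum at saccade start, the head→torso onset
delay, the ±80° neck range, and fixation-duration/count targets.

A trial is a kinematic chain driven by a fixation-target schedule:

1. **Schedule.**  Gamma-distributed fixation durations (shape 6, posture
   mean ≈ 186–194 ms) separated by 15–35 ms saccadic transitions fill the
   10 s; ≈ 44–47 fixations result.
2. **Targets.**  Exploratory targets are drawn i.i.d. from a centered
   anisotropic truncated Gaussian; with probability `local_prob`
   (0.62–0.69 by posture) the next target is instead a 3.6–6.5°
   "refixation" step, and a quarter of exploratory saccades revisit a
   previously fixated region.  Clustering and revisits give scanpaths the
   cap overlap that puts coverage near 2%, the step floor of 3.6° keeps
   refixations from merging inside one dispersion window, and a minimum
   target separation of 3.4° guards the same property for revisits.
3. **Eyes lead.**  Gaze lands on the target over the transition (slerped,
   minimum-jerk time profile) and is stable during fixations.
4. **Head follows.**  After a 60 ms oculomotor lead the head moves along a
   minimum-jerk trajectory that ends, exactly at fixation end, at a
   residual offset from the gaze point, so eccentricity reaches its
   minimum at the next saccade's start.  Minimum-jerk segments have zero
   terminal velocity, which is what lets the onset detector's hysteresis
   close between movements.
5. **Torso follows the head.**  The torso tracks a fixed fraction of gaze
   longitude (the ratio of configured torso to gaze spread) and starts a
   posture-dependent delay (±8 ms event jitter) after the head onset —
   and only when the head movement exceeds 5°, since a gaze step absorbed
   by the eyes recruits neither.  Head-minus-torso saturates softly at the
   neck range; in the sit posture (torso pinned near zero) this piles
   probability into side lobes near ±70°, while the free postures never
   reach the knee.  In swivel, the chair yaw carries the difference
   between torso-in-space and torso-relative-chair motion.
6. **Noise.**  Eye vectors get 0.2° white angular noise (tracker
   accuracy), head quaternions 0.05° rotation noise, and torso/chair yaw a
   slowly wandering AR(1) offset (1.5°/1.0° RMS, τ = 10 s): tracker error
   is a drifting bias; modeling it white would swamp any velocity-based
   onset detector.

Per-subject random effects: 10% multiplicative lognormal jitter on all
spreads and ±2° uniform jitter on latitude biases, drawn once per subject
so the repeated-measures structure is real.  All randomness flows from a
single `SeedSequence`; identical seeds reproduce experiments
byte-for-byte.

### Solved, not painted on

Several profile parameters are *realized* statistics, so the generator
solves its internals for them rather than injecting them directly:

- the truncated-Gaussian base σ is solved (Brent) so the draw SD equals
  the configured spread despite truncation at the reachable range, and the
  draw target is widened by a fixed 5% (`_SD_INFLATION`) because the
  pooled sample SD of a subject's trials runs about that much below the
  draw SD (transit dwell between targets, the centered trial start, and
  the downward bias of an SD estimated from cluster-correlated samples);
  torso/chair tracking gains carry the matching 1/0.95 (`_TRANSIT_DILUTION`);
- the head's end-of-fixation residual is solved by quadrature over the
  target distribution so the *event-average* eccentricity minimum equals
  the configured value even though sit-posture neck saturation leaves a
  subset of events more eccentric;
- the constructed eyes-in-head latitude bias is the configured bias
  divided by the time-average cos(horizontal eccentricity) of the
  profile's own dynamics, because pitch appears in the measured
  eyes-in-head latitude attenuated by that factor.  A consequence worth
  noting: with gaze centered near the equator and a measured eyes-in-head
  bias of about −10°, the realized head bias necessarily lands near
  +14…16° — the three reported biases are mutually consistent only
  through this attenuation.

Gaze mean latitude is centered within ±2.2° of the equator; the head bias
absorbs the remainder of the nominal sum.

### What the generator does not emulate

Image-content-driven saliency (targets are distribution-matched, not
scene-matched); realistic per-trial *total distance* — i.i.d. exploratory
targets produce larger saccade amplitudes, and therefore larger summed
travel, than human scanpaths with the same positional spread; vertical
head/eye kinematics beyond static biases; smooth pursuit, VOR gain, blinks
and tracker dropouts (the detector supports validity masks, the generator
does not emit them); and eye-in-head excursions are unbounded during large
transitions, where a human would use a head-and-eye staircase.  Passing
recovery tests therefore demonstrates that the pipeline measures what the
generator encodes — not that the generator is a complete model of human
exploration.

## Problem sizes used in the test suite

The recovery suite runs one full-size experiment (27 × 3 × 30 = 2430
trials, seed 1) through the complete pipeline and checks recovered spreads
(±10%), eccentricity minima (±1.5°), onset delays (±12 ms), the posture
ANOVA, bias composition, bimodality structure, and the saccade-locked
profile shape.  The spread-ordering property (sit < swivel < stand for
eyes, head, and torso) is checked across 20 replicate experiments of 27
subjects × 10 trials per posture — the between-subject jitter, not the
trial count, dominates the ordering noise, so shorter replicates test the
same property at a fraction of the cost.  Oracle suites use 1000-point
geometry batches, 50 brute-force event streams, and 20 Monte-Carlo
coverage sets of 10⁶ points.

## Numerical choices and edge cases

Longitude canonical range [−180, 180), poles canonicalized to lon 0;
quaternions scalar-first, renormalized on ingestion and rejected beyond
1e−3 norm deviation; q and −q are the same rotation.  Linear (not
circular) SDs for longitude: trials start centered and condition spreads
stay below ~90°, far from wrap saturation — a documented limitation for
distributions approaching uniformity.  Sample SD (ddof = 1) at the subject
level throughout.  Stream synchronization clamps edges to the nearest
native sample and refuses gaps > 100 ms.  Empty inputs return empty
results (no fixations, empty profiles with NaN curves) rather than
fabricated values; zero-variance inputs to t tests are flagged, and a
zero-variance ANOVA dependent variable is rejected.  KDE-based mode
finding uses Scott's bandwidth with a topographic-prominence criterion
(default 20% of the density maximum; the side-peak checks use 8% since
the ±70° lobes ride on a broad central distribution).
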