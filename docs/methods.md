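# Methods

`infantmotion` quantifies the spontaneous movements of supine infants from
single-camera video. This note documents the models and procedures the
package implements, the defaults and why they were chosen, what the
synthetic scenes do and do not emulate, and the numerical decisions that
were genuinely open.

## Problem setting

Qualitative assessment of infant general movements predicts
neurodevelopmental outcome but requires trained observers. A light-weight
alternative is to film the infant from above with one ordinary camera and
extract quantitative movement descriptors. Two obstacles shape the design:

1. **No metric scale.** One camera cannot give absolute distances, and the
   pixel size varies with resolution and camera height. All trajectories
   are therefore expressed in *head lengths*: the operator marks the
   forehead-to-chin line once per video and every coordinate is divided by
   its pixel length. A second operator-drawn line (clavicle midpoint to
   inferior pelvis margin) fixes the body orientation; trajectories are
   rigidly rotated so that +y always points caudally, making per-axis
   features mean medio-lateral (x) and cranio-caudal (y) regardless of how
   the camera was rolled.
2. **Tracking needs supervision.** Fully automatic limb detection in home
   videos is unreliable, so tracking is *semi-automatic*: the operator
   clicks each end effector (hand/foot center) once, a point tracker
   follows it, and the operator intervenes only when tracking fails or the
   limb is hidden. In this library the operator is abstracted into a
   `ResetProvider` callback, so scripted sessions and ground-truth-backed
   benchmarks replace the GUI.

## Tracking

Each end-effector point is followed with a pyramidal, translation-only
Kanade–Lucas–Tomasi tracker: a square template around the previous
position is registered against the next frame by Gauss–Newton iterations
on the SSD cost, coarse-to-fine over a 2-level Gaussian pyramid. A match
is accepted only if all three gates pass:

* **search window** — the matched point must lie inside an axis-aligned
  square of side 25% of the head length centered on the previous point.
  This is a hard constraint, not a hint: infant limbs cannot plausibly
  move half a head length between frames at 12.5 Hz, so larger jumps are
  treated as failures.
* **forward–backward error** — re-tracking the matched point back into the
  previous frame must land within 1 px of the start.
* **appearance** — the normalized cross-correlation between template and
  matched patch must reach `quality_threshold` (default 0.5). This is
  what detects occlusion onset: when a limb slips behind the body the
  patch under the stale template stops resembling it.

On rejection the `ResetProvider` is consulted: a supplied point is
recorded as a *reset* (a tracking failure in the failure-rate statistic),
a *skip* marks the frame missing while keeping the last valid template
anchored (used while a limb is hidden), and an *abstention* leaves the
frame missing and suspends tracking until the provider next supplies a
point. Because the template always comes from the last valid frame, short
occlusions do not corrupt it, and on a synthetic scene with a
truth-backed provider resets occur exactly at occlusion exits.

Template side is 10% of the head length (odd-rounded, minimum 5 px) —
large enough to span the textured core of a hand/foot, small enough not to
swallow background. The failure criterion (NCC + forward–backward) is an
implementation decision: the underlying method is published only as "KLT
with a search window", and any tracker needs *some* explicit acceptance
test to drive the skip/reset protocol.

The failure rate is 100 × (resets after frame 0) / N frames. Skips are
deliberately not failures: a hidden limb is an honest "no data", not a
tracker error.

## Trajectory preprocessing

* **Normalization**: divide by head length (per-video constant).
* **Reorientation**: rigid rotation about the symmetry-line midpoint
  mapping the symmetry line onto +y, head toward −y. Distances, hence
  speeds, are unchanged; only the per-axis decomposition is affected.
  All per-axis features are computed in this body frame so they are
  comparable across videos.
* **Gap interpolation**: interior missing runs of ≤ 5 samples are filled
  linearly (400 ms at the nominal 12.5 Hz). Longer runs and runs touching
  the recording boundary stay missing — interpolating across a long
  occlusion would fabricate a trend. Valid samples are never modified.

## Kinematic features

All features flag undefined values explicitly (`None`/NaN); a constant
trajectory yields zero velocity but *undefined* cross-correlation and
periodicity, never a silent 0.

* **Velocity** — Euclidean displacement between consecutive frames
  (head-lengths/frame; ×fps for head-lengths/s). The speed series is
  smoothed with a zero-phase (forward–backward) order-3 Butterworth
  low-pass at 0.95 of the Nyquist frequency, applied per contiguous valid
  segment; segments too short for the filter's edge padding (≤ 12
  samples) are left unfiltered. The cutoff barely attenuates physiological
  speeds; it clips only near-Nyquist jitter.
* **Acceleration** — one-lag difference of the (filtered) speed series.
* **Cross-correlation (CC)** — zero-lag normalized covariance
  σ_v1v2 / √(σ²_v1 σ²_v2) of two limbs' speed series over their common
  defined frames, for all six limb pairs; an index of inter-limb
  synchrony. Computed on the filtered speeds (they *are* the velocity
  after the filtering step); a config flag switches to raw.
* **Area from moving average (A_ma)** — per trajectory component, the sum
  of |x_i − x̄_i| over all samples where a centered 30-sample window fits,
  with x̄_i the centered moving average; a smoothness index. The window
  mean is taken over the k+1 = 31 points j = i−k/2 … i+k/2 divided by
  k+1. The variant that divides by k (which makes A_ma of a constant
  series nonzero and is best read as a typographical approximation of the
  mean) is available behind `ma_literal_divisor`. Upper/lower totals sum
  both components of both hands / both feet.
* **Periodicity (P)** — the series is cut into non-overlapping 500-sample
  windows (40 s at 12.5 Hz; trailing partial windows are discarded so d̄
  stays comparable across recording lengths). Per window, crossings of
  the component with the window mean are detected; distances between
  consecutive crossings are pooled (per axis, and per limb across both
  axes), giving d̄ (mean), σ_d (population SD) and P = 1/(d̄ + σ_d).
  Crossing detection uses strict sign changes; samples exactly on the
  mean adopt the sign of the previous off-mean sample (ties leftward),
  and crossings are never paired across a missing-data gap. Both pooled
  per-limb values (one P per limb) and per-axis values are emitted — the
  per-axis ones feed the z-contribution analysis.

Scale behavior, verified by property tests: velocity and A_ma scale
linearly with trajectory amplitude (hence inversely with head length);
CC, P, crossing counts and d̄ are amplitude-invariant.

## Motion images

The fully automatic feature family works on frame differences, no operator
involved: grayscale absolute difference → 5×5 median filter (kills
salt-and-pepper noise) → binarize above a threshold → 3×3 equal-weight
kernel. Three points the published pipeline leaves open, decided here:

* the binary map after the 3×3 kernel is re-binarized by **majority vote**
  (neighborhood mean ≥ 5/9), which deletes isolated pixels and preserves
  block interiors; the fraction is configurable;
* the default threshold is **15** on the 0–255 difference scale — the
  "optimal value" is scene-dependent and never published; an Otsu-based
  auto mode exists as a convenience and is not part of the validated
  pipeline;
* **Q is computed on the final binary map** (after the kernel), reading
  the motion image as the pipeline's end product.

Quantity of motion Q is the moving-pixel fraction; the centroid of motion
C is the mean coordinate of the moving pixels (the closed-form solution of
a one-cluster k-means, verified against an iterative k-means in tests).
Recording-level summaries: Q_mean/Q_sd/Q_max, C means and SDs, and mean/SD
of the centroid's speed and acceleration, where frames without motion
break the speed chain rather than being interpolated. Centroid statistics
stay in pixels — this feature family is not head-length-normalized.

## Validation statistics

* **Trajectory correlation** — per limb and axis, Pearson correlation at
  zero lag between two operators' pixel trajectories over jointly valid
  frames. Correlation compares trends, so constant click-offset between
  operators does not penalize it.
* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measure, from the two-way ANOVA mean squares:
  (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)). Implemented from
  scratch and cross-checked in tests against pingouin's ICC(A,1) and a
  planted variance-component simulation (σ²_target = 4, σ²_rater = 0.25,
  σ²_error = 0.25 → ICC = 8/9, recovered within 0.05 at n = 200).
  Point estimates only; no confidence intervals.
* **z-contribution** — for depth-augmented (N×3) trajectories, the share
  100·f_z/(f_x+f_y+f_z) of each per-axis feature (A_ma, crossing count,
  d̄, P), quantifying what a 2D analysis misses. The library accepts
  already-3D trajectories; camera-side depth registration is out of scope.

## Synthetic scenes

The generator renders what the pipeline needs to be testable, not a
photorealistic infant: a low-contrast filtered-noise background (standing
in for the blanket — textured, so the tracker has false structure to
reject), four Gaussian-profile blobs as end effectors, occlusions modeled
by simply not drawing a blob, Gaussian plus salt-and-pepper sensor noise.
Defaults mirror the recording conditions the pipeline targets: 12.5 Hz,
3-minute duration, head length 60 px in a 320×240 frame, four sinusoidal
limbs with periods 2–4.5 s and excursions under half a head length —
slow, smooth oscillations in the range of infant limb movements. Noise
defaults (σ = 2 intensity units, salt-and-pepper probability 5×10⁻⁴) are
mild consumer-camera levels.

Randomness is split into independent streams (background, sensor noise,
rater jitter) derived from one master seed, so changing the noise level
never changes trajectories. `make_rater_pair` produces two independently
jittered copies of the ground truth to exercise the inter-rater
statistics.

What the scenes do **not** emulate: articulated bodies, limb-over-limb
appearance change (occlusion is disappearance, not covering), lighting
drift, camera shake, or a moving trunk. Passing the synthetic benchmarks
therefore demonstrates correctness of the algorithms under known ground
truth — sub-pixel tracking, exact skip/reset bookkeeping, formula-level
feature correctness — not field performance on real infants, which
depends on operator skill and video quality.

## Numerical choices and problem sizes

* Standard deviations (σ_d, Q_sd, C_sd, V_sd, A_sd) are population SDs
  (ddof = 0); the convention is unstated in the source metrics and chosen
  once.
* CC and trajectory correlation use population covariance/variance over
  the overlap; constant series → undefined, never 0/0.
* LK normal equations with |det| < 1e-6 (textureless patch) are treated
  as failure; iteration stops at a 0.01 px step or 30 iterations.
* The benchmark suite uses 100–750-frame scenes (8–60 s at 12.5 Hz) and
  1000-sample series for oracle comparisons; these sizes make every
  statistic it checks well-determined while keeping a full run under a
  minute.

## Known limitations

* Single-point-per-limb tracking: no skeleton, no identity enforcement —
  crossing limbs are caught by the window/quality gates (or a reset), not
  by joint reasoning.
* The Butterworth cutoff at 0.95 Nyquist is so close to the band edge
  that its practical effect is small; it is kept for fidelity to the
  validated pipeline rather than for signal-processing merit.
* Container video I/O depends on the codecs available to imageio at run
  time; the guaranteed-lossless interchange formats are multi-page TIFF
  and PNG sequences.
* The motion-image threshold is global and fixed per run; scenes with
  illumination drift need the threshold revisited (or the non-validated
  auto mode).
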