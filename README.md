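# infantmotion

Quantitative analysis of infant spontaneous movements from single-camera
video.

Spontaneous "general movements" in the first months of life carry
diagnostic information: their quality predicts cerebral palsy and other
neurodevelopmental disorders, but standard assessment relies on trained
observers watching video. `infantmotion` implements a semi-automatic
pipeline that turns an ordinary overhead recording of a supine infant into
objective movement descriptors, for researchers studying early motor
development and for anyone building screening tools on top of such
recordings.

## What it computes

**Tracking.** One reference point per limb (hand/foot center) is followed
with a pyramidal Kanade–Lucas–Tomasi tracker constrained to a search
square of side 0.25·L_head centered on the previous position, where
L_head is the operator-measured forehead–chin distance in pixels. The
interactive operator of a GUI session is abstracted into a
`ResetProvider` callback (re-set the point / skip hidden frames), so
sessions are scriptable and reproducible. Tracking failures are counted
as `failure_rate = 100 · #resets / N`.

**Kinematic features** (on head-length-normalized, body-frame-reoriented,
gap-interpolated trajectories):

- mean velocity and acceleration, with the speed series
  v_t = ‖p_t − p_{t−1}‖ low-pass filtered (Butterworth order 3, cutoff
  0.95 f_Nyq, zero-phase);
- inter-limb synchrony CC = σ_{v1v2} / √(σ²_{v1} σ²_{v2}) for all six
  limb pairs;
- smoothness A_ma = Σ_i |x_i − x̄_i|, the area between each trajectory
  component and its centered 30-sample moving average;
- periodicity from mean-crossing intervals in 500-sample (40 s) windows:
  crossing count Tin, mean distance d̄, SD σ_d, and P = 1/(d̄ + σ_d).

**Motion-image features** (fully automatic): consecutive frames are
differenced, median-filtered (5×5), thresholded and cleaned with a 3×3
majority kernel into binary motion images, from which the quantity of
motion Q (moving-pixel fraction) and centroid of motion C (mean moving
pixel, the one-cluster k-means solution) are summarized.

**Validation statistics**: per-axis zero-lag correlation between two
operators' trajectories, ICC(2,1) (two-way random, absolute agreement,
single measure) per feature across videos, and the z-axis contribution
100·f_z/(f_x+f_y+f_z) for depth-augmented trajectories.

A synthetic-scene generator (textured background, four moving blobs with
known trajectories, occlusions, sensor noise, fully seeded) provides
ground truth for every stage; see `docs/methods.md` for the models,
defaults and their rationale.

## Worked example

```python
import numpy as np
import infantmotion as im

# a 60 s synthetic recording: four sinusoidal limbs, 12.5 Hz, 60 px head
spec = im.default_scene(duration=60.0, seed=42)
seq, gt = im.render_scene(spec)
cal = gt.calibration

inits = {limb: gt.centers[limb][0] for limb in im.LIMBS}
trajs = im.track_all(seq, inits, cal, gt.reset_provider())

pre = {l: im.preprocess(trajs[l], cal, seq.fps) for l in im.LIMBS}
feats = im.compute_kinematic_features(pre, seq.fps)
motion = im.motion_feature_summary(im.video_motion_images(seq), seq.fps)
```

Output of the full script (tracking error vs ground truth, then features):

```
right_hand  rmse=0.50 px  failure_rate=0.0%
left_hand   rmse=0.54 px  failure_rate=0.0%
right_foot  rmse=0.59 px  failure_rate=0.0%
left_foot   rmse=0.45 px  failure_rate=0.0%
right_hand mean velocity = 0.0613 head-lengths/frame (0.767 hl/s)
right_hand A_ma x/y = 139.60 / 141.00 head-lengths
right_hand periodicity: Tin=58, d_mean=17.1, d_sd=2.6 samples, P=0.0508
CC(right_hand, left_hand) = -0.027
Q_mean=0.0067  Q_max=0.0084  centroid=(157.6, 125.9) px
```

Reading these numbers: the tracker stays within ~0.5 px of the true blob
centers with no operator intervention; the right hand moves on average
0.06 head lengths per frame; its trajectory crosses its windowed mean
every ~17 samples with little spread (strongly periodic motion, as
expected for a pure sinusoid, P ≈ 0.05); the hands' speed profiles are
essentially uncorrelated (CC ≈ 0) because the limbs oscillate at
unrelated periods; and about 0.7% of the image changes per frame, with
the centroid of motion near the image center, between the four limbs.

## Command line

The same stages are available as subcommands:

```sh
infantmotion simulate --out-dir scene/ --seed 5 --duration 60
infantmotion track --video scene/video.tif --calibration scene/calibration.json \
    --init-points init.json --out tracked.csv
infantmotion features --trajectories tracked.csv --calibration scene/calibration.json \
    --out features
infantmotion motion --video scene/video.tif --out motion
infantmotion validate --trajectories-a runA.csv --trajectories-b runB.csv --out corr.csv
```

Lossless interchange formats are multi-page TIFF and PNG-sequence
directories; other containers are read when imageio has a codec plugin
for them. All tunables live in a JSON `RunConfig` echoed into every
output.

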