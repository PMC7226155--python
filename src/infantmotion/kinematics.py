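"""Kinematic feature battery from tracked limb trajectories.

The pipeline mirrors the standard general-movements feature set: tracked
pixel trajectories are reoriented into the body frame, normalized by head
length, short tracking gaps are filled by linear interpolation, and from
the preprocessed paths the battery is computed per limb:

* mean velocity and mean acceleration (speed = Euclidean inter-frame
  displacement, low-pass filtered);
* zero-lag cross-correlation (CC) of the speed series for all six limb
  pairs — an index of inter-limb synchrony;
* area from moving average (A_ma) per trajectory component — summed
  absolute deviation from a 30-sample centered moving average, an index of
  movement smoothness, plus upper/lower-limb totals;
* periodicity (P) — intersections of each component with its windowed mean
  give inter-crossing distances whose mean d̄ and spread σ_d combine into
  P = 1/(d̄ + σ_d), an index of repetitive movement.

Undefined values (constant series, too-short segments, missing limbs) are
explicit ``None`` / NaN markers, never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import signal

from .calibration import Calibration
from .tracking import LIMBS, Trajectory

__all__ = [
    "KinematicsConfig",
    "PreprocessedTrajectory",
    "interpolate_gaps",
    "preprocess",
    "speed_series",
    "butterworth_lowpass",
    "velocity",
    "acceleration",
    "cross_correlation",
    "area_from_moving_average",
    "mean_crossing_intervals",
    "periodicity",
    "compute_kinematic_features",
]

_AXES = ("x", "y", "z")
LIMB_PAIRS = tuple(combinations(LIMBS, 2))


@dataclass(frozen=True)
class KinematicsConfig:
    """Tunables of the feature battery.

    max_gap              : longest missing run (samples) filled by linear
                           interpolation; 5 samples = 400 ms at 12.5 Hz
    butter_order         : Butterworth low-pass order for the speed series
    butter_cutoff        : cutoff as a fraction of the Nyquist frequency
    ma_window            : moving-average window k (samples); 30 ≈ the
                           2-s averaging horizon of the source metric
    ma_literal_divisor   : divide the (k+1)-sample window sum by k instead
                           of k+1 (the printed-formula variant; the default
                           true mean keeps A_ma of a constant at 0)
    periodicity_window   : samples per mean-crossing window; 500 = 40 s
    cc_on_filtered       : correlate filtered (True) or raw speed series
    """

    max_gap: int = 5
    butter_order: int = 3
    butter_cutoff: float = 0.95
    ma_window: int = 30
    ma_literal_divisor: bool = False
    periodicity_window: int = 500
    cc_on_filtered: bool = True


@dataclass
class PreprocessedTrajectory:
    """Normalized, reoriented, gap-filled trajectory ready for features."""

    points: np.ndarray  # N×D head-length units, NaN at missing frames
    missing: np.ndarray
    fps: float
    limb: str = ""

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_axes(self) -> int:
        return self.points.shape[1]


# -- preprocessing ---------------------------------------------------------


def interpolate_gaps(
    points: np.ndarray, missing: np.ndarray, max_gap: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Fill interior missing runs of length ≤ ``max_gap`` linearly.

    Longer runs, and runs touching either end of the recording, are left
    missing: interpolating across a long invisible stretch would fabricate
    a trend.  Original valid samples are never modified.
    """
    points = np.asarray(points, dtype=float).copy()
    missing = np.asarray(missing, dtype=bool).copy()
    n = len(missing)
    valid_idx = np.flatnonzero(~missing)
    if valid_idx.size < 2:
        return points, missing
    for a, b in zip(valid_idx[:-1], valid_idx[1:]):
        gap = b - a - 1
        if 0 < gap <= max_gap:
            frac = (np.arange(a + 1, b) - a) / (b - a)
            points[a + 1 : b] = points[a][None, :] + frac[:, None] * (points[b] - points[a])
            missing[a + 1 : b] = False
    points[missing] = np.nan
    return points, missing


def preprocess(
    traj: Trajectory,
    cal: Calibration,
    fps: float,
    config: KinematicsConfig | None = None,
) -> PreprocessedTrajectory:
    """Pixel trajectory → body-frame, head-length-normalized, gap-filled.

    Reorientation (a rigid in-plane rotation) precedes normalization so the
    x/y components consistently mean medio-lateral/cranio-caudal; both maps
    are linear so their order does not affect any feature.
    """
    cfg = config or KinematicsConfig()
    pts = traj.points.copy()
    pts_r = pts.copy()
    pts_r[~traj.missing] = cal.reorient(pts[~traj.missing])
    pts_n = cal.normalize(pts_r)
    filled, still_missing = interpolate_gaps(pts_n, traj.missing, cfg.max_gap)
    return PreprocessedTrajectory(
        points=filled, missing=still_missing, fps=fps, limb=traj.limb
    )


# -- velocity / acceleration ----------------------------------------------


def speed_series(points: np.ndarray) -> np.ndarray:
    """Per-frame speed: Euclidean displacement between consecutive frames.

    Length-N array; entry t is the speed from frame t−1 to t, NaN when
    either frame is missing (entry 0 is always NaN).
    """
    points = np.asarray(points, dtype=float)
    v = np.full(points.shape[0], np.nan)
    d = np.diff(points, axis=0)
    v[1:] = np.sqrt(np.nansum(d**2, axis=1))
    v[1:][np.any(np.isnan(d), axis=1)] = np.nan
    return v


def butterworth_lowpass(
    series: np.ndarray, order: int = 3, cutoff: float = 0.95
) -> np.ndarray:
    """Zero-phase Butterworth low-pass applied per contiguous valid segment.

    The filter is run forward–backward (filtfilt) so it adds no phase lag;
    its DC gain is exactly 1, so constant speeds pass unchanged.  Segments
    too short for the filtfilt edge padding (≤ 3·(2·order+1) samples) are
    left unfiltered rather than producing edge artifacts.
    """
    b, a = signal.butter(order, cutoff)
    padlen = 3 * max(len(a), len(b))
    out = np.asarray(series, dtype=float).copy()
    n = len(out)
    valid = ~np.isnan(out)
    t = 0
    while t < n:
        if not valid[t]:
            t += 1
            continue
        end = t
        while end < n and valid[end]:
            end += 1
        if end - t > padlen:
            out[t:end] = signal.filtfilt(b, a, out[t:end])
        t = end
    return out


def velocity(
    traj: PreprocessedTrajectory, config: KinematicsConfig | None = None
) -> dict:
    """Speed series (raw and filtered) and the mean speed.

    Means are in head-lengths/frame; ``mean_per_s`` multiplies by fps.
    Undefined (no two consecutive valid frames) is flagged as None.
    """
    cfg = config or KinematicsConfig()
    raw = speed_series(traj.points)
    filt = butterworth_lowpass(raw, cfg.butter_order, cfg.butter_cutoff)
    defined = ~np.isnan(filt)
    mean = float(np.mean(filt[defined])) if defined.any() else None
    return {
        "raw": raw,
        "filtered": filt,
        "mean": mean,
        "mean_per_s": None if mean is None else mean * traj.fps,
    }


def acceleration(speed: np.ndarray, fps: float | None = None) -> dict:
    """One-lag difference of the speed series, with its mean.

    Defined at t where speeds t and t−1 are both defined; chains broken by
    missing frames are not bridged.
    """
    speed = np.asarray(speed, dtype=float)
    a = np.full_like(speed, np.nan)
    a[1:] = speed[1:] - speed[:-1]
    defined = ~np.isnan(a)
    mean = float(np.mean(a[defined])) if defined.any() else None
    return {
        "series": a,
        "mean": mean,
        "mean_per_s2": None if (mean is None or fps is None) else mean * fps**2,
    }


# -- cross-correlation (inter-limb synchrony) ------------------------------


def cross_correlation(v1: np.ndarray, v2: np.ndarray) -> float | None:
    """Zero-lag cross-correlation of two speed series.

    CC = σ_v1v2 / sqrt(σ²_v1 · σ²_v2) over the frames where both series are
    defined — the Pearson correlation of the two speeds.  Undefined (None)
    when the overlap has fewer than 2 frames or either series is constant
    on it.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    both = ~np.isnan(v1) & ~np.isnan(v2)
    if both.sum() < 2:
        return None
    a = v1[both] - v1[both].mean()
    b = v2[both] - v2[both].mean()
    var_a = np.mean(a**2)
    var_b = np.mean(b**2)
    if var_a == 0 or var_b == 0:
        return None
    return float(np.mean(a * b) / np.sqrt(var_a * var_b))


# -- area from moving average (smoothness) ---------------------------------


def area_from_moving_average(
    series: np.ndarray, k: int = 30, literal_divisor: bool = False
) -> float | None:
    """Summed absolute deviation of a component from its moving average.

    The moving average at sample i is centered, spanning j = i−k/2 .. i+k/2
    (k+1 samples); A_ma sums |x_i − x̄_i| over every i where the full window
    fits.  With the true (k+1)-sample mean a constant series scores exactly
    0; ``literal_divisor`` divides the window sum by k instead, matching
    the printed form of the metric at the cost of that property.

    Undefined (None) when the series is not longer than k or no window is
    NaN-free.
    """
    x = np.asarray(series, dtype=float)
    l = x.size
    if l <= k:
        return None
    divisor = k if literal_divisor else k + 1
    kernel = np.ones(k + 1) / divisor
    # convolution output index j corresponds to center i = j + k//2
    ma = np.convolve(x, kernel, mode="valid")
    center = x[k // 2 : k // 2 + ma.size]
    dev = np.abs(center - ma)
    defined = ~np.isnan(dev)
    if not defined.any():
        return None
    return float(np.sum(dev[defined]))


# -- periodicity (mean-crossing intervals) ---------------------------------


def mean_crossing_intervals(
    series: np.ndarray, window: int = 500
) -> tuple[int, np.ndarray]:
    """Crossings of a component with its per-window mean.

    The series is cut into non-overlapping windows of ``window`` samples
    (a trailing partial window is discarded so d̄ stays comparable across
    recording lengths).  Within each window the mean over valid samples is
    computed and sign changes of (x − mean) between consecutive valid
    samples are counted as crossings; samples exactly on the mean adopt the
    sign of the previous off-mean sample.  Returns the total crossing count
    and the array of distances (in samples) between consecutive crossings
    within each window.
    """
    x = np.asarray(series, dtype=float)
    n_windows = x.size // window
    total = 0
    distances: list[float] = []
    for w in range(n_windows):
        seg = x[w * window : (w + 1) * window]
        valid = ~np.isnan(seg)
        if valid.sum() < 2:
            continue
        m = np.mean(seg[valid])
        s = np.sign(seg - m)
        s[~valid] = np.nan
        # on-mean samples take the previous off-mean sign (leftward ties)
        prev = 0.0
        filled = np.zeros_like(s)
        for i, si in enumerate(s):
            if np.isnan(si):
                filled[i] = np.nan
                prev = 0.0  # a gap breaks the sign chain
            elif si == 0.0:
                filled[i] = prev
            else:
                filled[i] = si
                prev = si
        last_cross: int | None = None
        for i in range(len(seg) - 1):
            a, b = filled[i], filled[i + 1]
            if np.isnan(a) or np.isnan(b):
                last_cross = None  # do not pair crossings across a gap
                continue
            if a != 0 and b != 0 and a != b:
                total += 1
                if last_cross is not None:
                    distances.append(float(i - last_cross))
                last_cross = i
    return total, np.asarray(distances, dtype=float)


def periodicity(
    series: np.ndarray, window: int = 500
) -> dict:
    """Periodicity statistics of one trajectory component.

    Returns {tin, d_mean, d_sd, P}: total crossings, mean and SD
    (population) of the inter-crossing distances, and P = 1/(d̄ + σ_d).
    Fewer than two crossings leave d̄/σ_d/P undefined (None).
    """
    tin, distances = mean_crossing_intervals(series, window)
    if distances.size == 0:
        return {"tin": tin, "d_mean": None, "d_sd": None, "P": None}
    d_mean = float(np.mean(distances))
    d_sd = float(np.std(distances))
    return {"tin": tin, "d_mean": d_mean, "d_sd": d_sd, "P": 1.0 / (d_mean + d_sd)}


def _pooled_periodicity(per_axis: dict[str, tuple[int, np.ndarray]]) -> dict:
    tin = sum(t for t, _ in per_axis.values())
    pooled = np.concatenate([d for _, d in per_axis.values()]) if per_axis else np.array([])
    if pooled.size == 0:
        return {"tin": tin, "d_mean": None, "d_sd": None, "P": None}
    d_mean = float(np.mean(pooled))
    d_sd = float(np.std(pooled))
    return {"tin": tin, "d_mean": d_mean, "d_sd": d_sd, "P": 1.0 / (d_mean + d_sd)}


# -- full battery ----------------------------------------------------------


def compute_kinematic_features(
    trajs: dict[str, PreprocessedTrajectory],
    fps: float | None = None,
    config: KinematicsConfig | None = None,
) -> dict:
    """Assemble the full kinematic feature battery for a recording.

    ``trajs`` maps limb names to preprocessed trajectories (absent limbs
    yield None-flagged features).  Returns a nested dict: per-limb scalars,
    the 6-pair CC matrix, per-axis A_ma and periodicity, upper/lower A_ma
    totals, and pooled per-limb periodicity.
    """
    cfg = config or KinematicsConfig()
    limbs_out: dict[str, dict] = {}
    speeds: dict[str, np.ndarray] = {}

    for limb in LIMBS:
        tr = trajs.get(limb)
        if tr is None:
            limbs_out[limb] = {
                "mean_velocity": None,
                "mean_velocity_per_s": None,
                "mean_acceleration": None,
                "a_ma": {},
                "periodicity_per_axis": {},
                "periodicity": {"tin": None, "d_mean": None, "d_sd": None, "P": None},
            }
            continue
        vel = velocity(tr, cfg)
        acc = acceleration(vel["filtered"], tr.fps)
        speeds[limb] = vel["filtered"] if cfg.cc_on_filtered else vel["raw"]
        axes = _AXES[: tr.n_axes]
        a_ma = {
            ax: area_from_moving_average(tr.points[:, i], cfg.ma_window, cfg.ma_literal_divisor)
            for i, ax in enumerate(axes)
        }
        crossings = {
            ax: mean_crossing_intervals(tr.points[:, i], cfg.periodicity_window)
            for i, ax in enumerate(axes)
        }
        per_axis = {
            ax: periodicity(tr.points[:, i], cfg.periodicity_window)
            for i, ax in enumerate(axes)
        }
        limbs_out[limb] = {
            "mean_velocity": vel["mean"],
            "mean_velocity_per_s": vel["mean_per_s"],
            "mean_acceleration": acc["mean"],
            "a_ma": a_ma,
            "periodicity_per_axis": per_axis,
            "periodicity": _pooled_periodicity(crossings),
        }

    cc = {}
    for l1, l2 in LIMB_PAIRS:
        if l1 in speeds and l2 in speeds:
            cc[f"{l1}|{l2}"] = cross_correlation(speeds[l1], speeds[l2])
        else:
            cc[f"{l1}|{l2}"] = None

    def total(group: tuple[str, ...]) -> float | None:
        vals = [
            v
            for limb in group
            for v in limbs_out[limb]["a_ma"].values()
            if v is not None
        ]
        return float(np.sum(vals)) if vals else None

    return {
        "limbs": limbs_out,
        "cross_correlation": cc,
        "a_ma_total_upper": total(("right_hand", "left_hand")),
        "a_ma_total_lower": total(("right_foot", "left_foot")),
    }
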