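"""Reliability and dimensionality statistics.

The semi-automatic tracker involves an operator, so the tool's usefulness
hinges on operator-independence.  This module implements the corresponding
checks: zero-lag correlation between trajectories produced by two raters,
ICC(2,1) — the two-way random-effects, absolute-agreement, single-measure
intraclass correlation — for the extracted features, and the z-axis
contribution analysis quantifying how much of a per-axis feature a
single-camera (2D) setup misses relative to depth-augmented (3D) data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tracking import LIMBS, Trajectory

__all__ = [
    "trajectory_correlation",
    "icc_2_1",
    "z_contribution",
    "compare_operators",
]

_AXES = ("x", "y", "z")


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    both = ~np.isnan(a) & ~np.isnan(b)
    if both.sum() < 2:
        return None
    x = a[both] - a[both].mean()
    y = b[both] - b[both].mean()
    denom = np.sqrt(np.sum(x * x) * np.sum(y * y))
    if denom == 0:
        return None
    return float(np.sum(x * y) / denom)


def trajectory_correlation(
    trajA: dict[str, Trajectory], trajB: dict[str, Trajectory]
) -> pd.DataFrame:
    """Zero-lag Pearson correlation between two raters' trajectories.

    Computed per limb and per axis on raw pixel coordinates over the frames
    valid in both runs; being correlation it compares trends, so a constant
    offset between the raters' click positions does not lower it.  Returns
    a tidy frame (limb, axis, correlation), NaN where undefined.
    """
    rows = []
    for limb in trajA:
        a, b = trajA[limb], trajB[limb]
        if a.n_frames != b.n_frames:
            raise ValueError(f"trajectory length mismatch for {limb}")
        for i in range(min(a.n_axes, b.n_axes)):
            r = _pearson(a.points[:, i], b.points[:, i])
            rows.append({"limb": limb, "axis": _AXES[i], "correlation": np.nan if r is None else r})
    return pd.DataFrame(rows)


def icc_2_1(ratings: np.ndarray) -> float | None:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an n(targets) × k(raters) matrix with no missing cells.
    From the two-way ANOVA mean squares (MSR rows/targets, MSC columns/
    raters, MSE residual):

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    Returns None when the matrix has no variance at all (agreement is
    vacuous) or the denominator vanishes.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n×k matrix with n>=2, k>=2")
    if np.isnan(x).any():
        raise ValueError("ratings matrix must have no missing cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(x, grand):
        return None
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return None
    return float((msr - mse) / denom)


def z_contribution(per_axis_features: dict) -> pd.DataFrame:
    """Share of a per-axis feature carried by the depth (z) axis.

    ``per_axis_features`` maps (feature, limb) to {"x": v, "y": v, "z": v};
    the contribution is 100·f_z/(f_x+f_y+f_z) percent.  Quantifies the
    information a 2D single-camera analysis loses versus a 3D acquisition.
    Zero-sum entries are NaN-flagged.
    """
    rows = []
    for (feature, limb), axes in per_axis_features.items():
        fx, fy, fz = (axes.get(ax) for ax in _AXES)
        if None in (fx, fy, fz):
            pct = np.nan
        else:
            total = fx + fy + fz
            pct = np.nan if total == 0 else 100.0 * fz / total
        rows.append({"feature": feature, "limb": limb, "z_contribution_pct": pct})
    return pd.DataFrame(rows)


def compare_operators(
    features_a: dict[str, list[float]], features_b: dict[str, list[float]]
) -> pd.DataFrame:
    """ICC(2,1) per feature across a set of recordings rated by two operators.

    Each dict maps a feature name to its per-video values (same video order
    in both).  Videos where either operator's value is undefined (None/NaN)
    are dropped for that feature; features left with fewer than two videos
    are NaN-flagged.
    """
    rows = []
    for feat in features_a:
        a = np.array([np.nan if v is None else v for v in features_a[feat]], dtype=float)
        b = np.array([np.nan if v is None else v for v in features_b[feat]], dtype=float)
        if a.size != b.size:
            raise ValueError(f"operator value counts differ for feature {feat}")
        ok = ~np.isnan(a) & ~np.isnan(b)
        if ok.sum() < 2:
            icc = None
        else:
            icc = icc_2_1(np.column_stack([a[ok], b[ok]]))
        rows.append({"feature": feat, "icc": np.nan if icc is None else icc, "n_videos": int(ok.sum())})
    return pd.DataFrame(rows)
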