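"""Independent brute-force reference implementations used only by tests.

Each oracle is written as a direct, loop-based transcription of the
definition it checks, deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def pearson_cc(v1, v2) -> float:
    """Zero-lag cross-correlation: covariance over sqrt of variances."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    m1, m2 = v1.mean(), v2.mean()
    cov = sum((a - m1) * (b - m2) for a, b in zip(v1, v2)) / len(v1)
    var1 = sum((a - m1) ** 2 for a in v1) / len(v1)
    var2 = sum((b - m2) ** 2 for b in v2) / len(v2)
    return cov / np.sqrt(var1 * var2)


def area_ma(x, k=30, literal=False) -> float:
    """Moving-average deviation area, direct double loop."""
    x = np.asarray(x, dtype=float)
    l = len(x)
    total = 0.0
    for i in range(k // 2, l - k // 2):
        window = [x[j] for j in range(i - k // 2, i + k // 2 + 1)]
        xbar = sum(window) / (k if literal else k + 1)
        total += abs(x[i] - xbar)
    return total


def crossing_stats(x, window=500):
    """Mean-crossing intervals: per-window mean, strict sign changes,
    on-mean samples take the previous off-mean sign; distances between
    consecutive crossings within a window."""
    x = np.asarray(x, dtype=float)
    tin = 0
    dists = []
    for w in range(len(x) // window):
        seg = x[w * window : (w + 1) * window]
        m = seg.mean()
        signs = []
        prev = 0
        for v in seg:
            s = int(v > m) - int(v < m)
            if s == 0:
                s = prev
            else:
                prev = s
            signs.append(s)
        last = None
        for i in range(len(seg) - 1):
            if signs[i] != 0 and signs[i + 1] != 0 and signs[i] != signs[i + 1]:
                tin += 1
                if last is not None:
                    dists.append(i - last)
                last = i
    return tin, dists


def periodicity_P(x, window=500):
    tin, dists = crossing_stats(x, window)
    if not dists:
        return tin, None, None, None
    d = np.asarray(dists, dtype=float)
    dbar = d.mean()
    sd = np.sqrt(((d - dbar) ** 2).mean())
    return tin, dbar, sd, 1.0 / (dbar + sd)


def kmeans_one_cluster(points, seed=0, iters=50):
    """Iterative k-means with k=1, run to convergence from a random init."""
    points = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)
    center = points[rng.integers(len(points))].astype(float)
    for _ in range(iters):
        new = points.mean(axis=0)  # every point belongs to the single cluster
        if np.allclose(new, center, atol=1e-12):
            break
        center = new
    return center


def motion_pipeline_reference(frame_t, frame_prev, threshold=15.0):
    """From-scratch motion-image pipeline with explicit loops.

    abs difference -> 5x5 median (reflect) -> >threshold -> 3x3 equal
    kernel, keep when the neighborhood mean is >= 5/9.
    """
    a = np.asarray(frame_t, dtype=float)
    b = np.asarray(frame_prev, dtype=float)
    diff = np.abs(a - b)
    padded = np.pad(diff, 2, mode="reflect")
    med = np.empty_like(diff)
    h, w = diff.shape
    for y in range(h):
        for x in range(w):
            med[y, x] = np.median(padded[y : y + 5, x : x + 5])
    binary = (med > threshold).astype(int)
    padded_b = np.pad(binary, 1, mode="reflect")
    out = np.empty_like(binary)
    for y in range(h):
        for x in range(w):
            mean9 = padded_b[y : y + 3, x : x + 3].sum() / 9.0
            out[y, x] = 1 if mean9 >= 5.0 / 9.0 - 1e-9 else 0
    return out.astype(np.uint8)


def icc_2_1_anova(x):
    """ICC(2,1) via explicit sums of squares of the two-way layout."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * sum((x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
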