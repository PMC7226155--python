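"""Pyramidal Lucas–Kanade point matcher.

Translation-only LK: a square template around the point in the previous
frame is registered against the next frame by Gauss–Newton iterations on
the sum-of-squared-differences cost, coarse-to-fine over a Gaussian
pyramid.  Match confidence is reported as the normalized cross-correlation
(NCC) between the template and the matched patch, together with the
forward–backward re-tracking error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["KLTResult", "lk_match", "lk_match_fb"]


@dataclass(frozen=True)
class KLTResult:
    point: np.ndarray | None  # matched (x, y) in the next frame, or None
    ncc: float                # template/patch correlation at the match
    fb_error: float           # forward-backward displacement error (px)
    converged: bool


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [img]
    for _ in range(levels - 1):
        smoothed = ndimage.gaussian_filter(pyr[-1], sigma=1.0, mode="nearest")
        pyr.append(smoothed[::2, ::2])
    return pyr


def _sample(img: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    # map_coordinates is (row, col) ordered
    return ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")


def _lk_single_level(
    prev: np.ndarray,
    nxt: np.ndarray,
    p: np.ndarray,
    guess: np.ndarray,
    half: int,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, bool]:
    """One pyramid level; returns (displacement, converged)."""
    offs = np.arange(-half, half + 1, dtype=float)
    gx, gy = np.meshgrid(offs, offs)
    xs = p[0] + gx.ravel()
    ys = p[1] + gy.ravel()

    template = _sample(prev, xs, ys)
    # spatial gradients of the template (central differences on the patch grid)
    ix = _sample(prev, xs + 0.5, ys) - _sample(prev, xs - 0.5, ys)
    iy = _sample(prev, xs, ys + 0.5) - _sample(prev, xs, ys - 0.5)
    G = np.array([[np.sum(ix * ix), np.sum(ix * iy)], [np.sum(ix * iy), np.sum(iy * iy)]])
    if np.linalg.det(G) < 1e-6:  # textureless patch: the normal equations are singular
        return guess, False

    d = guess.astype(float).copy()
    Ginv = np.linalg.inv(G)
    for _ in range(max_iter):
        patch = _sample(nxt, xs + d[0], ys + d[1])
        err = template - patch
        b = np.array([np.sum(ix * err), np.sum(iy * err)])
        step = Ginv @ b
        d += step
        if np.hypot(*step) < tol:
            return d, True
    return d, False


def lk_match(
    prev: np.ndarray,
    nxt: np.ndarray,
    point: np.ndarray,
    patch_half: int,
    levels: int = 2,
    max_iter: int = 30,
    tol: float = 0.01,
) -> tuple[np.ndarray, float, bool]:
    """Match ``point`` from ``prev`` into ``nxt``.

    Returns (matched point, NCC quality, converged).  Images are float
    grayscale; ``patch_half`` is the template half-width in pixels at full
    resolution.
    """
    point = np.asarray(point, dtype=float)
    pyr_prev = _pyramid(np.asarray(prev, dtype=np.float32), levels)
    pyr_next = _pyramid(np.asarray(nxt, dtype=np.float32), levels)

    d = np.zeros(2)
    converged = True
    for lvl in range(levels - 1, -1, -1):
        scale = 2.0**lvl
        half_lvl = max(2, int(round(patch_half / scale)))
        d_lvl, ok = _lk_single_level(
            pyr_prev[lvl], pyr_next[lvl], point / scale, d / scale, half_lvl, max_iter, tol
        )
        d = d_lvl * scale
        converged = converged and ok

    matched = point + d
    ncc = _patch_ncc(prev, nxt, point, matched, patch_half)
    return matched, ncc, converged


def _patch_ncc(
    prev: np.ndarray, nxt: np.ndarray, p: np.ndarray, q: np.ndarray, half: int
) -> float:
    offs = np.arange(-half, half + 1, dtype=float)
    gx, gy = np.meshgrid(offs, offs)
    a = _sample(np.asarray(prev, dtype=np.float32), p[0] + gx.ravel(), p[1] + gy.ravel())
    b = _sample(np.asarray(nxt, dtype=np.float32), q[0] + gx.ravel(), q[1] + gy.ravel())
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0:
        return 0.0
    return float(np.sum(a * b) / denom)


def lk_match_fb(
    prev: np.ndarray,
    nxt: np.ndarray,
    point: np.ndarray,
    patch_half: int,
    levels: int = 2,
    max_iter: int = 30,
    tol: float = 0.01,
) -> KLTResult:
    """Forward match plus backward re-track for a self-consistency error."""
    fwd, ncc, ok_f = lk_match(prev, nxt, point, patch_half, levels, max_iter, tol)
    back, _, ok_b = lk_match(nxt, prev, fwd, patch_half, levels, max_iter, tol)
    fb = float(np.hypot(*(back - np.asarray(point, dtype=float))))
    return KLTResult(point=fwd, ncc=ncc, fb_error=fb, converged=ok_f and ok_b)
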