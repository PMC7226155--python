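"""Motion images and image-based movement features.

Whereas the tracking pipeline needs an operator, these features are fully
automatic: consecutive frames are differenced, denoised and binarized into
a *motion image* marking the pixels that changed due to movement, from
which the quantity of motion Q (fraction of moving pixels) and the centroid
of motion C (mean position of the moving pixels — exactly the one-cluster
k-means solution) are computed per frame and summarized over the recording.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .video_io import VideoSequence, to_grayscale

__all__ = [
    "MotionConfig",
    "motion_image",
    "video_motion_images",
    "quantity_of_motion",
    "centroid_of_motion",
    "motion_feature_summary",
    "save_motion_images",
]


@dataclass(frozen=True)
class MotionConfig:
    """Motion-image pipeline tunables.

    threshold         : binarization level on the 0–255 absolute-difference
                        scale ("optimal" is scene-dependent; 15 suppresses
                        sensor noise while keeping genuine limb motion)
    median_size       : salt-and-pepper median filter window (5×5)
    kernel_size       : equal-weight smoothing kernel on the binary map (3×3)
    majority_fraction : neighborhood mean needed to keep a pixel after the
                        kernel (5/9 = majority vote: isolated pixels vanish,
                        block interiors survive)
    auto_threshold    : derive the threshold per frame pair by Otsu's method
                        on the difference histogram instead of ``threshold``
                        (a convenience mode, not part of the validated
                        pipeline)
    """

    threshold: float = 15.0
    median_size: int = 5
    kernel_size: int = 3
    majority_fraction: float = 5.0 / 9.0
    auto_threshold: bool = False


def _otsu(diff: np.ndarray) -> float:
    hist, edges = np.histogram(diff.ravel(), bins=256, range=(0, 256))
    p = hist.astype(float) / max(hist.sum(), 1)
    omega = np.cumsum(p)
    mu = np.cumsum(p * np.arange(256))
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1
    return float(np.argmax(sigma_b))


def motion_image(
    frame_t: np.ndarray,
    frame_prev: np.ndarray,
    threshold: float | None = None,
    config: MotionConfig | None = None,
) -> np.ndarray:
    """Binary map of the pixels that moved between two consecutive frames.

    Pipeline: grayscale absolute difference → 5×5 median filter (removes
    salt-and-pepper noise) → binarize above the threshold → 3×3 equal-weight
    kernel with a majority vote (removes residual isolated noise pixels).
    Both filters use reflect padding at the borders.
    """
    cfg = config or MotionConfig()
    if threshold is not None:
        cfg = MotionConfig(**{**cfg.__dict__, "threshold": threshold})
    a = to_grayscale(np.asarray(frame_t)).astype(np.float64)
    b = to_grayscale(np.asarray(frame_prev)).astype(np.float64)
    if a.shape != b.shape:
        raise ValueError(f"frame size mismatch: {a.shape} vs {b.shape}")
    diff = np.abs(a - b)
    diff = ndimage.median_filter(diff, size=cfg.median_size, mode="reflect")
    thr = _otsu(diff) if cfg.auto_threshold else cfg.threshold
    binary = (diff > thr).astype(np.uint8)
    counts = ndimage.convolve(
        binary.astype(np.int32), np.ones((cfg.kernel_size, cfg.kernel_size), dtype=np.int32),
        mode="reflect",
    )
    needed = cfg.majority_fraction * cfg.kernel_size**2
    return (counts >= needed - 1e-9).astype(np.uint8)


def video_motion_images(
    seq: VideoSequence, config: MotionConfig | None = None
) -> Iterator[np.ndarray]:
    """Motion images for t = 1..N−1 of a sequence (lazy)."""
    for t in range(1, seq.n_frames):
        yield motion_image(seq.frames[t], seq.frames[t - 1], config=config)


def quantity_of_motion(mi: np.ndarray) -> float:
    """Fraction of image pixels marked as moving: Q = (#ones)/(H·W)."""
    mi = np.asarray(mi)
    return float(np.count_nonzero(mi) / mi.size)


def centroid_of_motion(mi: np.ndarray) -> tuple[float, float] | None:
    """Mean (x, y) of the movement pixels, or None for an empty map.

    The arithmetic mean of the member coordinates is the fixed point of a
    one-cluster k-means, so no iteration is needed.
    """
    ys, xs = np.nonzero(np.asarray(mi))
    if xs.size == 0:
        return None
    return float(xs.mean()), float(ys.mean())


def motion_feature_summary(
    images: Iterable[np.ndarray], fps: float | None = None
) -> dict:
    """Recording-level summary of Q and C.

    Q statistics (mean, population SD, max) cover every motion image.
    Centroid statistics cover the frames where C is defined; the centroid
    speed is the displacement between *consecutive* defined centroids and
    its one-lag difference is the centroid acceleration — frames with no
    motion break the chain rather than being interpolated.  Centroid
    coordinates are in pixels.  Undefined summaries are None.
    """
    qs: list[float] = []
    cents: list[tuple[float, float] | None] = []
    for mi in images:
        qs.append(quantity_of_motion(mi))
        cents.append(centroid_of_motion(mi))
    q = np.asarray(qs, dtype=float)
    out: dict = {
        "Q_mean": float(q.mean()) if q.size else None,
        "Q_sd": float(q.std()) if q.size else None,
        "Q_max": float(q.max()) if q.size else None,
        "Q_series": q,
    }
    cx = np.array([c[0] if c else np.nan for c in cents])
    cy = np.array([c[1] if c else np.nan for c in cents])
    defined = ~np.isnan(cx)
    if defined.any():
        out.update(
            C_xmean=float(np.mean(cx[defined])),
            C_ymean=float(np.mean(cy[defined])),
            C_xsd=float(np.std(cx[defined])),
            C_ysd=float(np.std(cy[defined])),
        )
    else:
        out.update(C_xmean=None, C_ymean=None, C_xsd=None, C_ysd=None)
    out["C_series"] = np.column_stack([cx, cy]) if cx.size else np.empty((0, 2))

    # centroid speed: consecutive defined centroids only
    v = np.full(len(cents), np.nan)
    for i in range(1, len(cents)):
        if defined[i] and defined[i - 1]:
            v[i] = float(np.hypot(cx[i] - cx[i - 1], cy[i] - cy[i - 1]))
    a = np.full(len(cents), np.nan)
    a[1:] = v[1:] - v[:-1]
    vd, ad = ~np.isnan(v), ~np.isnan(a)
    out.update(
        V_mean=float(np.mean(v[vd])) if vd.any() else None,
        V_sd=float(np.std(v[vd])) if vd.any() else None,
        A_mean=float(np.mean(a[ad])) if ad.any() else None,
        A_sd=float(np.std(a[ad])) if ad.any() else None,
        V_series=v,
        A_series=a,
    )
    return out


def save_motion_images(
    images: Iterable[np.ndarray], out_dir: str | os.PathLike
) -> None:
    """Dump motion images as a 0/255 PNG sequence for visual inspection."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t, mi in enumerate(images, start=1):
        iio.imwrite(out / f"motion_{t:05d}.png", (np.asarray(mi) * 255).astype(np.uint8))
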