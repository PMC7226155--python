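"""Synthetic supine-infant scenes with known ground truth.

Real recordings of infants cannot ship with a library, so every stage of
the pipeline is exercised on rendered stand-ins: a low-contrast textured
background (emulating the blanket the infant lies on), four bright limb
blobs moving along parametric trajectories, optional occlusion intervals
during which a blob is simply not drawn (a limb hidden behind the body),
and sensor noise.  The renderer returns the exact blob-center trajectories
and visibility masks, so tracking error and every downstream feature can be
scored against truth.

All randomness derives from a single master seed through independent
per-component streams: toggling the noise level never changes the
trajectories or the background.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .calibration import Calibration
from .tracking import LIMBS, GroundTruthResetProvider, Trajectory
from .video_io import VideoSequence

__all__ = [
    "LimbSpec",
    "SceneSpec",
    "GroundTruth",
    "trajectory_model",
    "render_scene",
    "make_rater_pair",
    "default_scene",
]

_STREAMS = {"background": 0, "noise": 1}


class SceneConfigError(ValueError):
    """Invalid scene specification (unknown model, blob leaving the frame...)."""


def trajectory_model(
    kind: str, params: dict, n_frames: int, fps: float
) -> np.ndarray:
    """Evaluate a parametric 2D path, N×2 pixels.

    Kinds
    -----
    constant : {center}
    linear   : {start, velocity} with velocity in px/frame
    sinusoid : {center, amplitude, period, phase}; per-axis values may be
               scalars (shared) or (x, y) pairs; period in seconds;
               x(t) = cx + A·sin(2πt/T + φ) and likewise for y
    sum_of_sinusoids : {center, components: [{amplitude, period, phase}, ...]}
    jerky    : {start, step, hold, seed} — piecewise-constant random velocity
               of magnitude ``step`` px/frame redrawn every ``hold`` frames
    """
    t = np.arange(n_frames) / fps

    def pair(v) -> np.ndarray:
        a = np.asarray(v, dtype=float)
        return np.array([a, a]) if a.ndim == 0 else a

    if kind == "constant":
        c = pair(params["center"])
        return np.tile(c, (n_frames, 1))
    if kind == "linear":
        start = pair(params["start"])
        vel = pair(params["velocity"])  # px/frame
        return start + np.arange(n_frames)[:, None] * vel
    if kind == "sinusoid":
        c, A, T, ph = (pair(params[k]) for k in ("center", "amplitude", "period", "phase"))
        return c + A * np.sin(2 * np.pi * t[:, None] / T + ph)
    if kind == "sum_of_sinusoids":
        c = pair(params["center"])
        path = np.tile(c, (n_frames, 1))
        for comp in params["components"]:
            A, T, ph = pair(comp["amplitude"]), pair(comp["period"]), pair(comp["phase"])
            path = path + A * np.sin(2 * np.pi * t[:, None] / T + ph)
        return path
    if kind == "jerky":
        rng = np.random.default_rng(int(params.get("seed", 0)))
        start = pair(params["start"])
        step = float(params["step"])
        hold = int(params.get("hold", 8))
        n_segments = int(np.ceil(n_frames / hold))
        angles = rng.uniform(0, 2 * np.pi, n_segments)
        vel = step * np.column_stack([np.cos(angles), np.sin(angles)])
        per_frame = np.repeat(vel, hold, axis=0)[: n_frames - 1]
        return start + np.vstack([np.zeros(2), np.cumsum(per_frame, axis=0)])
    raise SceneConfigError(f"unknown trajectory model {kind!r}")


@dataclass
class LimbSpec:
    limb: str
    model: str
    params: dict
    radius: float = 6.0
    intensity: float = 150.0


@dataclass
class SceneSpec:
    """Full description of a rendered scene; the seed determines everything."""

    width: int = 320
    height: int = 240
    fps: float = 12.5
    duration: float = 180.0  # 3-minute segments, the standard analysis length
    head_line: tuple = ((160.0, 28.0), (160.0, 88.0))
    symmetry_line: tuple = ((160.0, 95.0), (160.0, 205.0))
    limbs: list[LimbSpec] = field(default_factory=list)
    occlusions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    noise_sigma: float = 2.0
    salt_pepper_prob: float = 0.0005
    background_mean: float = 60.0
    background_contrast: float = 12.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    def calibration(self) -> Calibration:
        hl = tuple(tuple(map(float, p)) for p in self.head_line)
        sl = tuple(tuple(map(float, p)) for p in self.symmetry_line)
        return Calibration(head_line=hl, symmetry_line=sl)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "width", "height", "fps", "duration", "noise_sigma",
                "salt_pepper_prob", "background_mean", "background_contrast", "seed",
            )
        }
        d["head_line"] = [list(p) for p in self.head_line]
        d["symmetry_line"] = [list(p) for p in self.symmetry_line]
        d["limbs"] = [
            {"limb": l.limb, "model": l.model, "params": l.params,
             "radius": l.radius, "intensity": l.intensity}
            for l in self.limbs
        ]
        d["occlusions"] = {k: [list(iv) for iv in v] for k, v in self.occlusions.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        d["head_line"] = tuple(tuple(p) for p in d["head_line"])
        d["symmetry_line"] = tuple(tuple(p) for p in d["symmetry_line"])
        d["limbs"] = [LimbSpec(**l) for l in d.get("limbs", [])]
        d["occlusions"] = {
            k: [tuple(iv) for iv in v] for k, v in d.get("occlusions", {}).items()
        }
        return cls(**d)

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "SceneSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class GroundTruth:
    """True blob-center trajectories, visibility, and the scene calibration."""

    centers: dict[str, np.ndarray]  # limb -> N×2 float pixels
    visible: dict[str, np.ndarray]  # limb -> N bool
    calibration: Calibration

    def reset_provider(self) -> GroundTruthResetProvider:
        return GroundTruthResetProvider(self.centers, self.visible)

    def trajectories(self) -> dict[str, Trajectory]:
        out = {}
        for limb, pts in self.centers.items():
            missing = ~self.visible[limb]
            p = pts.copy()
            p[missing] = np.nan
            out[limb] = Trajectory(limb=limb, points=p, missing=missing)
        return out


def _component_rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[component],))
    )


def _render_background(spec: SceneSpec) -> np.ndarray:
    rng = _component_rng(spec.seed, "background")
    raw = rng.standard_normal((spec.height, spec.width))
    smooth = ndimage.gaussian_filter(raw, sigma=3.0, mode="wrap")
    smooth /= max(smooth.std(), 1e-12)
    return np.clip(spec.background_mean + spec.background_contrast * smooth, 0, 255)


def _draw_blob(frame: np.ndarray, cx: float, cy: float, radius: float, intensity: float) -> None:
    # Gaussian profile with sigma = radius/2, truncated at 3 sigma; additive
    sigma = radius / 2.0
    extent = int(np.ceil(3 * sigma)) + 1
    x0, x1 = int(np.floor(cx)) - extent, int(np.floor(cx)) + extent + 1
    y0, y1 = int(np.floor(cy)) - extent, int(np.floor(cy)) + extent + 1
    x0, x1 = max(x0, 0), min(x1, frame.shape[1])
    y0, y1 = max(y0, 0), min(y1, frame.shape[0])
    ys, xs = np.mgrid[y0:y1, x0:x1]
    r2 = (xs - cx) ** 2 + (ys - cy) ** 2
    frame[y0:y1, x0:x1] += intensity * np.exp(-r2 / (2 * sigma**2))


def render_scene(spec: SceneSpec) -> tuple[VideoSequence, GroundTruth]:
    """Render a scene; bit-identical output under the same spec and seed."""
    n = spec.n_frames
    if n < 2:
        raise SceneConfigError("scene must span at least 2 frames")
    background = _render_background(spec)

    centers: dict[str, np.ndarray] = {}
    visible: dict[str, np.ndarray] = {}
    for limbspec in spec.limbs:
        path = trajectory_model(limbspec.model, limbspec.params, n, spec.fps)
        margin = limbspec.radius
        if (
            path[:, 0].min() < margin
            or path[:, 0].max() > spec.width - 1 - margin
            or path[:, 1].min() < margin
            or path[:, 1].max() > spec.height - 1 - margin
        ):
            raise SceneConfigError(f"blob for {limbspec.limb} leaves the frame")
        vis = np.ones(n, dtype=bool)
        for start, end in spec.occlusions.get(limbspec.limb, []):
            if not (0 <= start < end <= n):
                raise SceneConfigError(
                    f"occlusion [{start},{end}) outside [0,{n}) for {limbspec.limb}"
                )
            vis[start:end] = False
        centers[limbspec.limb] = path
        visible[limbspec.limb] = vis

    noise_rng = _component_rng(spec.seed, "noise")
    frames = np.empty((n, spec.height, spec.width), dtype=np.uint8)
    for t in range(n):
        frame = background.copy()
        for limbspec in spec.limbs:
            if visible[limbspec.limb][t]:
                cx, cy = centers[limbspec.limb][t]
                _draw_blob(frame, cx, cy, limbspec.radius, limbspec.intensity)
        if spec.noise_sigma > 0:
            frame = frame + noise_rng.normal(0, spec.noise_sigma, frame.shape)
        if spec.salt_pepper_prob > 0:
            u = noise_rng.random(frame.shape)
            frame[u < spec.salt_pepper_prob / 2] = 0
            frame[(u >= spec.salt_pepper_prob / 2) & (u < spec.salt_pepper_prob)] = 255
        frames[t] = np.clip(np.round(frame), 0, 255).astype(np.uint8)

    seq = VideoSequence(frames=frames, fps=spec.fps)
    gt = GroundTruth(centers=centers, visible=visible, calibration=spec.calibration())
    return seq, gt


def make_rater_pair(
    gt: GroundTruth, jitter_sigma: float, seed: int
) -> tuple[dict[str, Trajectory], dict[str, Trajectory]]:
    """Two independently jittered copies of the ground truth.

    Emulates two operators tracking the same recording: each rater's points
    are the true centers plus isotropic Gaussian jitter of the given sigma
    (pixels).  Used to exercise inter-operator correlation and ICC.
    """
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    raters = []
    for _ in range(2):
        trajs = {}
        for limb, pts in gt.centers.items():
            noisy = pts + rng.normal(0, jitter_sigma, pts.shape)
            missing = ~gt.visible[limb]
            noisy = noisy.copy()
            noisy[missing] = np.nan
            trajs[limb] = Trajectory(limb=limb, points=noisy, missing=missing)
        raters.append(trajs)
    return raters[0], raters[1]


def default_scene(
    duration: float = 180.0,
    seed: int = 0,
    noise_sigma: float = 2.0,
    salt_pepper_prob: float = 0.0005,
    occlusions: dict[str, list[tuple[int, int]]] | None = None,
) -> SceneSpec:
    """A supine-infant-like scene: four sinusoidal limbs, 12.5 Hz, 60 px head.

    Amplitudes and periods are in the range of slow infant limb
    oscillations (periods 2–4.5 s, excursions ≲ half a head length).
    """
    limbs = [
        LimbSpec("right_hand", "sinusoid",
                 {"center": [90, 70], "amplitude": [25, 18],
                  "period": [3.2, 2.4], "phase": [0.0, 1.1]}),
        LimbSpec("left_hand", "sinusoid",
                 {"center": [230, 70], "amplitude": [22, 20],
                  "period": [2.7, 3.6], "phase": [0.8, 0.3]}),
        LimbSpec("right_foot", "sinusoid",
                 {"center": [100, 185], "amplitude": [28, 15],
                  "period": [4.0, 2.0], "phase": [0.4, 2.0]}),
        LimbSpec("left_foot", "sinusoid",
                 {"center": [220, 185], "amplitude": [24, 17],
                  "period": [3.0, 4.5], "phase": [1.6, 0.9]}),
    ]
    return SceneSpec(
        duration=duration,
        seed=seed,
        limbs=limbs,
        noise_sigma=noise_sigma,
        salt_pepper_prob=salt_pepper_prob,
        occlusions=occlusions or {},
    )
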