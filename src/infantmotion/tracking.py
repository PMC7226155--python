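"""End-effector tracking.

One reference point per limb (hand or foot center) is followed frame by
frame with a pyramidal Lucas–Kanade matcher.  The search is constrained to
a square of side 25% of the head length centered on the previous position:
infant limbs cannot plausibly move further between frames at ~12.5 Hz, and
the constraint rejects most false matches outright.

When a match is rejected (poor appearance correlation, forward–backward
inconsistency, or a jump outside the search window) a :class:`ResetProvider`
is consulted — the programmatic counterpart of the operator who, in an
interactive session, either re-clicks the point or skips frames where the
limb is hidden behind other body segments.
"""

from __future__ import annotations

import csv
import enum
import os
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from ._klt import lk_match_fb
from .calibration import Calibration
from .video_io import VideoSequence

__all__ = [
    "LIMBS",
    "Trajectory",
    "TrackerConfig",
    "ResetAction",
    "ResetProvider",
    "GroundTruthResetProvider",
    "ScriptedResetProvider",
    "null_reset_provider",
    "track_limb",
    "track_all",
    "failure_rate",
    "save_trajectories",
    "load_trajectories",
]

#: Canonical limb order used in every multi-limb output.
LIMBS = ("right_hand", "left_hand", "right_foot", "left_foot")


@dataclass
class Trajectory:
    """Per-limb point sequence with missing-frame bookkeeping.

    ``points`` is N×2 (or N×3 for depth-augmented data); rows at missing
    frames hold NaN and must never be used.  ``resets`` lists the frames at
    which the point was supplied externally; frame 0 (the initial manual
    selection) is always a reset.
    """

    limb: str
    points: np.ndarray
    missing: np.ndarray
    resets: list[int] = field(default_factory=lambda: [0])
    units: str = "px"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.points.shape[0] != self.missing.shape[0]:
            raise ValueError("points and missing mask length mismatch")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_axes(self) -> int:
        return self.points.shape[1]

    def valid_points(self) -> np.ndarray:
        return self.points[~self.missing]


class ResetActionKind(enum.Enum):
    SET = "set"
    SKIP = "skip"
    ABSTAIN = "abstain"


@dataclass(frozen=True)
class ResetAction:
    kind: ResetActionKind
    point: tuple[float, float] | None = None

    @classmethod
    def set(cls, x: float, y: float) -> "ResetAction":
        return cls(ResetActionKind.SET, (float(x), float(y)))

    @classmethod
    def skip(cls) -> "ResetAction":
        return cls(ResetActionKind.SKIP)

    @classmethod
    def abstain(cls) -> "ResetAction":
        return cls(ResetActionKind.ABSTAIN)


class ResetProvider(Protocol):
    """Operator stand-in: asked for help at frames where tracking fails."""

    def __call__(self, frame: int, limb: str) -> ResetAction: ...


def null_reset_provider(frame: int, limb: str) -> ResetAction:
    """Provider that never intervenes (fully automatic run)."""
    return ResetAction.abstain()


class GroundTruthResetProvider:
    """Reset provider backed by known true positions and visibility.

    Skips frames where the limb is occluded and re-sets the point to its
    true position otherwise — the idealized attentive operator used to
    benchmark the tracker against synthetic scenes.
    """

    def __init__(self, centers: dict[str, np.ndarray], visible: dict[str, np.ndarray]):
        self.centers = {k: np.asarray(v, dtype=float) for k, v in centers.items()}
        self.visible = {k: np.asarray(v, dtype=bool) for k, v in visible.items()}

    def __call__(self, frame: int, limb: str) -> ResetAction:
        if not self.visible[limb][frame]:
            return ResetAction.skip()
        x, y = self.centers[limb][frame, :2]
        return ResetAction.set(x, y)


class ScriptedResetProvider:
    """Replays a recorded operator session.

    The script maps (frame, limb) to an action; unknown keys abstain.  The
    CSV dialect is ``frame,limb,action,x,y`` with action in {set, skip}.
    """

    def __init__(self, events: dict[tuple[int, str], ResetAction]):
        self.events = events

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "ScriptedResetProvider":
        events: dict[tuple[int, str], ResetAction] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                key = (int(row["frame"]), row["limb"])
                if row["action"] == "set":
                    events[key] = ResetAction.set(float(row["x"]), float(row["y"]))
                elif row["action"] == "skip":
                    events[key] = ResetAction.skip()
                else:
                    raise ValueError(f"unknown reset action {row['action']!r}")
        return cls(events)

    def __call__(self, frame: int, limb: str) -> ResetAction:
        return self.events.get((frame, limb), ResetAction.abstain())


@dataclass(frozen=True)
class TrackerConfig:
    """Tunables of the matcher; fractions are of the head length.

    ``search_window_fraction`` is the full side of the search square
    (default 0.25, i.e. accepted matches lie within ±0.125 head lengths of
    the previous point per axis).  ``patch_fraction`` sizes the LK template.
    ``quality_threshold`` is the minimum template/patch NCC; ``fb_max_px``
    the maximum forward–backward re-tracking error.
    """

    search_window_fraction: float = 0.25
    patch_fraction: float = 0.1
    quality_threshold: float = 0.5
    fb_max_px: float = 1.0
    pyramid_levels: int = 2
    max_iterations: int = 30
    convergence_tol: float = 0.01


def _patch_half(cfg: TrackerConfig, head_length: float) -> int:
    side = max(5, int(round(cfg.patch_fraction * head_length)))
    if side % 2 == 0:
        side += 1
    return side // 2


def track_limb(
    seq: VideoSequence,
    limb: str,
    init_point: Sequence[float],
    cal: Calibration,
    resets: ResetProvider = null_reset_provider,
    quality_threshold: float | None = None,
    config: TrackerConfig | None = None,
) -> Trajectory:
    """Track one end effector through the whole sequence.

    The template is always taken from the last frame where the point was
    valid, so short occlusions handled by skips do not corrupt it.  After
    the provider abstains, tracking stays un-anchored (frames missing) until
    the provider supplies a new point.
    """
    cfg = config or TrackerConfig()
    if quality_threshold is not None:
        cfg = TrackerConfig(**{**cfg.__dict__, "quality_threshold": quality_threshold})
    if seq.n_frames < 2:
        raise ValueError("tracking needs at least 2 frames")
    x0, y0 = float(init_point[0]), float(init_point[1])
    if not (0 <= x0 < seq.width and 0 <= y0 < seq.height):
        raise ValueError(f"init point ({x0},{y0}) outside {seq.width}x{seq.height} frame")

    head_length = cal.head_length
    half_window = cfg.search_window_fraction * head_length / 2.0
    patch_half = _patch_half(cfg, head_length)

    n = seq.n_frames
    points = np.full((n, 2), np.nan)
    missing = np.ones(n, dtype=bool)
    reset_frames = [0]
    points[0] = (x0, y0)
    missing[0] = False

    last_valid = 0  # frame index of the template/search anchor
    anchored = True
    gray_cache: dict[int, np.ndarray] = {}

    def gray(t: int) -> np.ndarray:
        if t not in gray_cache:
            if len(gray_cache) > 4:
                gray_cache.clear()
            gray_cache[t] = seq.gray(t)
        return gray_cache[t]

    for t in range(1, n):
        accepted = False
        if anchored:
            prev_pt = points[last_valid]
            res = lk_match_fb(
                gray(last_valid),
                gray(t),
                prev_pt,
                patch_half,
                levels=cfg.pyramid_levels,
                max_iter=cfg.max_iterations,
                tol=cfg.convergence_tol,
            )
            if (
                res.converged
                and res.fb_error <= cfg.fb_max_px
                and res.ncc >= cfg.quality_threshold
                and np.all(np.abs(res.point - prev_pt) <= half_window)
                and 0 <= res.point[0] < seq.width
                and 0 <= res.point[1] < seq.height
            ):
                points[t] = res.point
                missing[t] = False
                last_valid = t
                accepted = True
        if not accepted:
            action = resets(t, limb)
            if action.kind is ResetActionKind.SET:
                points[t] = action.point
                missing[t] = False
                reset_frames.append(t)
                last_valid = t
                anchored = True
            elif action.kind is ResetActionKind.SKIP:
                pass  # limb not visible: frame stays missing, anchor kept
            else:  # abstain: re-anchor only at the next provider-supplied point
                anchored = False

    return Trajectory(limb=limb, points=points, missing=missing, resets=reset_frames, units="px")


def track_all(
    seq: VideoSequence,
    init_points: dict[str, Sequence[float]],
    cal: Calibration,
    resets: ResetProvider = null_reset_provider,
    config: TrackerConfig | None = None,
) -> dict[str, Trajectory]:
    """Track all four limbs independently; output in canonical limb order."""
    missing_limbs = [l for l in LIMBS if l not in init_points]
    if missing_limbs:
        raise ValueError(f"init points missing for limbs: {missing_limbs}")
    return {
        limb: track_limb(seq, limb, init_points[limb], cal, resets, config=config)
        for limb in LIMBS
    }


def failure_rate(traj: Trajectory) -> float:
    """Tracking failure rate in percent.

    100 × (resets excluding the initial frame-0 selection) / total frames.
    Skipped frames (limb hidden) are not failures and do not count.
    """
    n_resets = sum(1 for f in traj.resets if f != 0)
    return 100.0 * n_resets / traj.n_frames


# -- trajectory CSV dialect ------------------------------------------------
# columns: frame, limb, x, y[, z], missing(0/1), reset(0/1); 0-based frames;
# missing rows carry empty coordinates.


def save_trajectories(trajs: dict[str, Trajectory], path: str | os.PathLike) -> None:
    rows = []
    for limb in trajs:
        tr = trajs[limb]
        has_z = tr.n_axes == 3
        for t in range(tr.n_frames):
            row = {
                "frame": t,
                "limb": limb,
                "x": "" if tr.missing[t] else repr(float(tr.points[t, 0])),
                "y": "" if tr.missing[t] else repr(float(tr.points[t, 1])),
                "missing": int(tr.missing[t]),
                "reset": int(t in tr.resets),
            }
            if has_z:
                row["z"] = "" if tr.missing[t] else repr(float(tr.points[t, 2]))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_trajectories(path: str | os.PathLike) -> dict[str, Trajectory]:
    df = pd.read_csv(path)
    has_z = "z" in df.columns
    out: dict[str, Trajectory] = {}
    for limb, g in df.groupby("limb", sort=False):
        g = g.sort_values("frame")
        n = len(g)
        d = 3 if has_z else 2
        points = np.full((n, d), np.nan)
        missing = g["missing"].to_numpy().astype(bool)
        cols = ["x", "y", "z"] if has_z else ["x", "y"]
        vals = g[cols].to_numpy(dtype=float)
        points[~missing] = vals[~missing]
        resets = [int(f) for f in g.loc[g["reset"] == 1, "frame"]]
        out[limb] = Trajectory(
            limb=str(limb), points=points, missing=missing, resets=resets or [0]
        )
    return out
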