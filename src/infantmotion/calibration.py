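"""Anthropometric calibration.

A single camera gives trajectories in pixels, a unit that depends on camera
resolution and distance and so cannot be compared across recordings.  Two
operator-drawn lines fix a per-video reference frame instead:

* the **head line** (forehead to chin) whose pixel length is the
  anthropometric unit used to normalize all trajectories, and
* the **symmetry line** (clavicle midpoint to inferior pelvis margin) which
  defines body orientation, so per-axis features mean medio-lateral (x) and
  cranio-caudal (y) consistently regardless of camera roll.

Coordinates follow the image convention: x = column, y = row, origin at the
top-left, 0-based.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

__all__ = ["Calibration", "CalibrationError", "load_calibration"]


class CalibrationError(ValueError):
    """Degenerate or out-of-bounds calibration geometry."""


@dataclass(frozen=True)
class Calibration:
    """Head-line and symmetry-line endpoints, in pixels.

    ``head_line``     : ((x,y), (x,y)) forehead → chin
    ``symmetry_line`` : ((x,y), (x,y)) clavicle midpoint → pelvis
    """

    head_line: tuple[tuple[float, float], tuple[float, float]]
    symmetry_line: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        for name in ("head_line", "symmetry_line"):
            a, b = getattr(self, name)
            if np.allclose(a, b):
                raise CalibrationError(f"{name} endpoints coincide: {a}")

    @property
    def head_length(self) -> float:
        """Euclidean head-line length in pixels — the normalization unit."""
        (x0, y0), (x1, y1) = self.head_line
        return float(np.hypot(x1 - x0, y1 - y0))

    @property
    def body_angle(self) -> float:
        """Angle (radians) of the symmetry line relative to the image +y axis."""
        (x0, y0), (x1, y1) = self.symmetry_line
        return float(np.arctan2(x1 - x0, y1 - y0))

    def validate_bounds(self, width: int, height: int) -> None:
        """Check all endpoints fall inside a ``width`` × ``height`` frame."""
        for name in ("head_line", "symmetry_line"):
            for x, y in getattr(self, name):
                if not (0 <= x < width and 0 <= y < height):
                    raise CalibrationError(
                        f"{name} endpoint ({x},{y}) outside {width}x{height} frame"
                    )

    # -- transforms -------------------------------------------------------

    def normalize(self, points: np.ndarray) -> np.ndarray:
        """Convert pixel coordinates to head-length units (divide by head length).

        Works on (..., 2) or (..., 3) arrays; NaNs (missing frames) pass
        through untouched.  The map is linear, so displacements and
        deviations scale with it: a feature measured in head lengths is
        invariant to spatial rescaling of the video.
        """
        return np.asarray(points, dtype=float) / self.head_length

    def rotation_matrix(self) -> np.ndarray:
        """2×2 rotation taking the symmetry line onto the +y image axis."""
        (x0, y0), (x1, y1) = self.symmetry_line
        dx, dy = x1 - x0, y1 - y0
        length = np.hypot(dx, dy)
        # R @ (dx,dy) == (0, length): clavicle end maps to smaller y (head up)
        return np.array([[dy, -dx], [dx, dy]]) / length

    def reorient(self, points: np.ndarray) -> np.ndarray:
        """Rotate trajectories into the standard body frame.

        A rigid rotation about the symmetry-line midpoint maps the symmetry
        line onto the +y axis with the head toward −y.  For (..., 3) input
        the rotation acts on x,y and leaves z (depth) unchanged.  Distances
        are preserved exactly, so speed-based features are unaffected; only
        the decomposition into per-axis components changes.
        """
        pts = np.asarray(points, dtype=float)
        squeeze = pts.ndim == 1
        pts = np.atleast_2d(pts).copy()
        (x0, y0), (x1, y1) = self.symmetry_line
        mid = np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0])
        R = self.rotation_matrix()
        pts[..., :2] = (pts[..., :2] - mid) @ R.T + mid
        return pts[0] if squeeze else pts

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "head_line": [list(p) for p in self.head_line],
            "symmetry_line": [list(p) for p in self.symmetry_line],
        }

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        def pair(key: str):
            (ax, ay), (bx, by) = d[key]
            return ((float(ax), float(ay)), (float(bx), float(by)))

        return cls(head_line=pair("head_line"), symmetry_line=pair("symmetry_line"))


def load_calibration(path: str | os.PathLike) -> Calibration:
    """Load a calibration JSON: ``{"head_line": [[x,y],[x,y]], "symmetry_line": ...}``."""
    with open(path) as fh:
        return Calibration.from_dict(json.load(fh))
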