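"""Run configuration: every tunable of the pipeline in one serializable
record, echoed into all outputs so a run can be reproduced exactly."""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

from .kinematics import KinematicsConfig
from .motion_images import MotionConfig
from .tracking import TrackerConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Defaults follow the validated pipeline: 25% head-length search
    window, 5-sample interpolation limit, order-3 Butterworth at 0.95
    Nyquist, 30-sample moving-average window, 500-sample periodicity
    window, motion threshold 15 with 5×5 median and 3×3 kernel."""

    fps_override: float | None = None
    seed: int = 0
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    motion: MotionConfig = field(default_factory=MotionConfig)

    def to_dict(self) -> dict:
        return {
            "fps_override": self.fps_override,
            "seed": self.seed,
            "tracker": asdict(self.tracker),
            "kinematics": asdict(self.kinematics),
            "motion": asdict(self.motion),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            fps_override=d.get("fps_override"),
            seed=int(d.get("seed", 0)),
            tracker=TrackerConfig(**d.get("tracker", {})),
            kinematics=KinematicsConfig(**d.get("kinematics", {})),
            motion=MotionConfig(**d.get("motion", {})),
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
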