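"""FeatureSet container: assembles kinematic and motion-image features for
one recording and serializes them as flat JSON or tidy CSV, with explicit
null markers for undefined values and the run configuration echoed for
provenance."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureSet"]


def _clean(obj):
    """Drop per-frame series, convert numpy scalars, keep None markers."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items() if not k.endswith("_series") and k != "series"}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, np.ndarray):
        return None
    return obj


@dataclass
class FeatureSet:
    """Full feature battery of one recording."""

    kinematic: dict = field(default_factory=dict)
    motion: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kinematic": _clean(self.kinematic),
            "motion": _clean(self.motion),
            "config": _clean(self.config),
        }

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_tidy(self) -> pd.DataFrame:
        """One row per feature × limb/pair/axis, value NaN when undefined."""
        rows: list[dict] = []

        def add(feature, value, limb="", pair="", axis=""):
            rows.append(
                {
                    "feature": feature,
                    "limb": limb,
                    "pair": pair,
                    "axis": axis,
                    "value": np.nan if value is None else value,
                    "defined": int(value is not None),
                }
            )

        kin = self.kinematic
        for limb, d in kin.get("limbs", {}).items():
            add("mean_velocity", d["mean_velocity"], limb=limb)
            add("mean_velocity_per_s", d["mean_velocity_per_s"], limb=limb)
            add("mean_acceleration", d["mean_acceleration"], limb=limb)
            for ax, v in d.get("a_ma", {}).items():
                add("a_ma", v, limb=limb, axis=ax)
            for ax, p in d.get("periodicity_per_axis", {}).items():
                for key in ("tin", "d_mean", "d_sd", "P"):
                    add(f"periodicity_{key}", p[key], limb=limb, axis=ax)
            pooled = d.get("periodicity", {})
            for key in ("tin", "d_mean", "d_sd", "P"):
                add(f"periodicity_{key}", pooled.get(key), limb=limb)
        for pair, v in kin.get("cross_correlation", {}).items():
            add("cross_correlation", v, pair=pair)
        add("a_ma_total_upper", kin.get("a_ma_total_upper"))
        add("a_ma_total_lower", kin.get("a_ma_total_lower"))

        for key, v in _clean(self.motion).items():
            add(key, v)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_tidy().to_csv(path, index=False)
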