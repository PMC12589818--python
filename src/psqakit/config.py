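"""Analysis configuration: defaults, YAML loading, validation.

Schema (all keys optional; shown with defaults)::

    grouping: both          # site | facility | both  (primary stratification)
    channels: ["3/3", "2/2", "dose_diff_pct"]
    beta: 6.0               # tolerance-width constant
    fence_k: 1.5            # Tukey fence multiplier for outlier alerts
    min_n: 20               # below this a stratum's limits are "provisional"
    alert_channel: "3/3"    # channel evaluated for breach/outlier alerts
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .limits import DEFAULT_BETA, DEFAULT_MIN_N

__all__ = ["AnalysisConfig", "load_config"]

_GROUPINGS = ("site", "facility", "both")


@dataclass(frozen=True)
class AnalysisConfig:
    grouping: str = "both"
    channels: tuple[str, ...] = ("3/3", "2/2", "dose_diff_pct")
    beta: float = DEFAULT_BETA
    fence_k: float = 1.5
    min_n: int = DEFAULT_MIN_N
    alert_channel: str = "3/3"

    def validate(self) -> "AnalysisConfig":
        if self.grouping not in _GROUPINGS:
            raise ValueError(f"grouping must be one of {_GROUPINGS}, got {self.grouping!r}")
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.fence_k < 0:
            raise ValueError(f"fence_k must be non-negative, got {self.fence_k}")
        if self.min_n < 2:
            raise ValueError(f"min_n must be at least 2, got {self.min_n}")
        return self

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "channels": list(self.channels),
            "beta": self.beta,
            "fence_k": self.fence_k,
            "min_n": self.min_n,
            "alert_channel": self.alert_channel,
        }


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Load a YAML config file, apply keyword overrides, validate."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(raw) - set(AnalysisConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(raw)
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "channels" in data:
        data["channels"] = tuple(data["channels"])
    return AnalysisConfig(**data).validate()
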