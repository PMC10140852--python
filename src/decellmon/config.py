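"""Run configuration: a strict, YAML-backed schema with rig defaults.

Defaults mirror the monitoring software's operating settings: a 10-sample
stop window with a 3 % band, 50 mL/h pump flow, and a 10 s frame interval.
Frame intervals carry an explicit unit tag (``s`` or ``min``) because the
rig was operated at both 10 s and 5 min cadences in different experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration content."""


_INTERVAL_UNITS = {"s": 1.0 / 60.0, "min": 1.0}


@dataclass
class RunConfig:
    """Validated configuration for a monitoring/simulation session."""

    time_get_photo: float = 10.0
    time_get_photo_unit: str = "s"
    stop_time_n: int = 10
    k_percent: float = 3.0
    smoothing_sigma: float = 2.0
    flow_rate_mL_per_h: float = 50.0
    seed: int = 0
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        problems = []
        if self.time_get_photo_unit not in _INTERVAL_UNITS:
            problems.append(
                f"time_get_photo_unit must be 's' or 'min', got {self.time_get_photo_unit!r}"
            )
        for name in ("time_get_photo", "k_percent", "smoothing_sigma", "flow_rate_mL_per_h"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0, got {getattr(self, name)}")
        if self.stop_time_n < 2:
            problems.append(f"stop_time_n must be >= 2, got {self.stop_time_n}")
        if not isinstance(self.seed, int) or self.seed < 0:
            problems.append(f"seed must be a nonnegative integer, got {self.seed!r}")
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))

    @property
    def frame_interval_min(self) -> float:
        """Frame interval converted to minutes."""
        return self.time_get_photo * _INTERVAL_UNITS[self.time_get_photo_unit]

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; missing keys take defaults.

    An empty file yields the all-defaults configuration.  Unknown keys and
    invalid values raise :class:`ConfigError` listing every offender.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {', '.join(unknown)}")
    return RunConfig(**raw)


def save_config(path: str | Path, config: RunConfig) -> Path:
    """Write a config as YAML; load_config round-trips it exactly."""
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path
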