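"""Analysis configuration with the package defaults.

Defaults mirror the reference imaging setup: 5 px filter length and grid
spacing, 25 px sampling-circle radius, minimum fiber count 10,
strong-alignment threshold 0.7, visualization threshold 0.8, 0.83 μm
pixels, 1 μm z-spacing, 0.05 histogram bins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class AnalysisConfig:
    filter_length: float = 5.0  # px, fiber quantization step
    spacing: float = 5.0  # px, grid interval
    circle_radius: float = 25.0  # px, local sampling circle
    min_fiber_count: int = 10  # strict: a valid cell needs > this many segments
    strong_threshold: float = 0.7  # strong-alignment ratio cutoff
    viz_threshold: float = 0.8  # 3D plots show cells above this
    pixel_size: float = 0.83  # μm per pixel
    z_spacing: float = 1.0  # μm between z-slices
    bin_width: float = 0.05  # alignment-histogram bin width

    def __post_init__(self) -> None:
        for name in ("filter_length", "spacing", "circle_radius", "pixel_size",
                     "z_spacing", "bin_width"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("strong_threshold", "viz_threshold"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.min_fiber_count < 0:
            raise ConfigError("min_fiber_count must be >= 0")

    @classmethod
    def from_file(cls, path: Union[str, Path], **overrides) -> "AnalysisConfig":
        """Load a YAML mapping of config fields; ``overrides`` win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path}: expected a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"config file {path}: unknown keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
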