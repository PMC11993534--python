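"""Run configuration: every tunable of the analysis pipeline in one object.

The effective configuration is serialized (YAML) next to each run's
outputs so results are reproducible; loading that file back yields an
equal config object.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError
from .image_io import DEFAULT_CHANNEL_MAP


@dataclass
class AnalysisConfig:
    channel_map: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    # preprocessing
    clahe_clip: float = 0.01
    clahe_grid: tuple[int, int] = (8, 8)
    gaussian_sigma: float = 1.5
    # nuclear segmentation
    threshold_window: int | None = None  # None -> 1/8 of min dimension, odd
    sweep_start: float = 0.0
    sweep_stop: float = 0.5
    sweep_points: int = 21
    min_area: int = 50
    keep_border: bool = False
    # matrix / vessel segmentation
    matrix_sensitivity: float = 0.05
    vessel_min_area: int = 50
    # orientation
    ocp_direction_deg: float = 90.0
    ocp_cone_half_angle_deg: float = 45.0
    ocp_max_distance: float = 150.0
    # texture
    glcm_levels: int = 8
    # cardiomyocyte selection
    selective: bool = True
    proximity_threshold: float = 15.0
    # misc
    debug_artifacts: bool = False
    seed: int = 0

    def sweep(self):
        import numpy as np

        if self.sweep_points < 5:
            raise ConfigError("sweep_points must be >= 5")
        return np.linspace(self.sweep_start, self.sweep_stop, self.sweep_points)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clahe_grid"] = list(self.clahe_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "clahe_grid" in d:
            d["clahe_grid"] = tuple(d["clahe_grid"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable hash of the effective configuration."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


__all__ = ["AnalysisConfig"]
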