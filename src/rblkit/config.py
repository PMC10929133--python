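"""Pipeline configuration with namespaced-key YAML loading."""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Tuple

import yaml


class ConfigError(ValueError):
    pass


#: YAML key -> attribute mapping (namespaced keys, e.g. ``crop.padding``)
_KEY_MAP = {
    "crop.padding": "crop_padding",
    "merge.min_pixels": "merge_min_pixels",
    "axis.source": "axis_source",
    "distance.mode": "distance_mode",
    "staging.t1": "stage_t1",
    "staging.t2": "stage_t2",
}


@dataclass
class PipelineConfig:
    crop_padding: int = 10
    merge_min_pixels: int = 1
    axis_source: str = "tooth"  # or "root"
    distance_mode: str = "axial"  # or "image_vertical"
    stage_t1: float = 15.0
    stage_t2: float = 33.0

    def __post_init__(self) -> None:
        if self.axis_source not in ("tooth", "root"):
            raise ConfigError(f"axis.source must be 'tooth' or 'root', got {self.axis_source!r}")
        if self.distance_mode not in ("axial", "image_vertical"):
            raise ConfigError(
                f"distance.mode must be 'axial' or 'image_vertical', got {self.distance_mode!r}"
            )
        if not (0 < self.stage_t1 < self.stage_t2):
            raise ConfigError(f"staging thresholds must satisfy 0 < t1 < t2, "
                              f"got {self.stage_t1}, {self.stage_t2}")
        if self.crop_padding < 0:
            raise ConfigError("crop.padding must be >= 0")

    @property
    def stage_thresholds(self) -> Tuple[float, float]:
        return (self.stage_t1, self.stage_t2)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"config {path!r} must be a mapping")
        kwargs = {}
        for key, value in doc.items():
            if key not in _KEY_MAP:
                raise ConfigError(f"unknown config key {key!r} (known: {sorted(_KEY_MAP)})")
            kwargs[_KEY_MAP[key]] = value
        return cls(**kwargs)
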