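"""Run configuration: one YAML file driving every command.

The config mirrors the library's parameter dataclasses section by
section; unknown keys are rejected so typos fail loudly, and a loaded
config round-trips through :meth:`RunConfig.to_yaml` unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .errors import ValidationError
from .morphometrics import DEFAULT_QUANTILE_LEVELS
from .segmentation import ManualParams, SegParams
from .synthetic import GrowthSpec, SceneSpec


@dataclass(frozen=True)
class RMCVOptions:
    blank_cycles: int = 5
    alpha: float = 0.01
    persistence: int = 3


def _build(cls, data: dict[str, Any], section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(
            f"unknown keys in config section '{section}': {sorted(unknown)}"
        )
    coerced = dict(data)
    for key in ("image_shape", "illumination_gradient"):
        if key in coerced and isinstance(coerced[key], list):
            coerced[key] = tuple(coerced[key])
    return cls(**coerced)


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a pipeline run, loadable from YAML."""

    seg: SegParams = field(default_factory=SegParams)
    manual: ManualParams = field(default_factory=ManualParams)
    scene: SceneSpec = field(default_factory=SceneSpec)
    growth: GrowthSpec = field(default_factory=GrowthSpec)
    rmcv: RMCVOptions = field(default_factory=RMCVOptions)
    quantile_levels: tuple[float, ...] = DEFAULT_QUANTILE_LEVELS
    min_area_um2: float | None = None
    output_dir: str = "."
    log_level: str = "INFO"
    seed: int = 0

    _SECTIONS = {
        "seg": SegParams,
        "manual": ManualParams,
        "scene": SceneSpec,
        "growth": GrowthSpec,
        "rmcv": RMCVOptions,
    }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key in cls._SECTIONS:
                kwargs[key] = _build(cls._SECTIONS[key], value or {}, key)
            elif key == "quantile_levels":
                kwargs[key] = tuple(float(v) for v in value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config {path} must be a YAML mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.integer):
                return int(obj)
            if isinstance(obj, np.floating):
                return float(obj)
            return obj

        return {
            "seg": plain(self.seg),
            "manual": plain(self.manual),
            "scene": plain(self.scene),
            "growth": plain(self.growth),
            "rmcv": plain(self.rmcv),
            "quantile_levels": list(self.quantile_levels),
            "min_area_um2": self.min_area_um2,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
            "seed": self.seed,
        }

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
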