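"""Validated run configuration.

A run is described by a YAML (or programmatic) configuration with four
blocks — geometry, material, schedule, calibration — plus output
directory, seed and log level.  Unknown keys are rejected before any
computation starts; CLI flags override file values.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .constitutive import DEFAULT_FLARE, DEFAULT_STACK, LayerMaterial, MaterialStack

__all__ = ["RunConfig", "GeometryConfig", "MaterialConfig", "ScheduleConfig", "CalibrationConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    bougie_fr: list[float] = Field(default=[27, 30, 34, 36, 38, 40, 42, 46, 48, 50, 54])
    length_mm: float = 150.0
    mucosa_thickness_mm: float = 1.0
    muscularis_thickness_mm: float = 1.5
    flare: float = DEFAULT_FLARE
    antrum_length_mm: float = 50.0
    end_taper_length_mm: float = 10.0
    junction_radius_mm: float = 3.0
    spacing_mm: float = 2.0


class LayerParams(_Strict):
    c_kpa: float
    a_dimless: float


class MaterialConfig(_Strict):
    mucosa: LayerParams = Field(
        default_factory=lambda: LayerParams(
            c_kpa=DEFAULT_STACK.mucosa.c_kpa, a_dimless=DEFAULT_STACK.mucosa.a_dimless
        )
    )
    muscularis: LayerParams = Field(
        default_factory=lambda: LayerParams(
            c_kpa=DEFAULT_STACK.muscularis.c_kpa,
            a_dimless=DEFAULT_STACK.muscularis.a_dimless,
        )
    )

    def stack(self) -> MaterialStack:
        return MaterialStack(
            mucosa=LayerMaterial("mucosa", self.mucosa.c_kpa, self.mucosa.a_dimless),
            muscularis=LayerMaterial(
                "muscularis", self.muscularis.c_kpa, self.muscularis.a_dimless
            ),
        )


class ScheduleConfig(_Strict):
    pressures_mmhg: list[float] = Field(default=[7.5, 15.0, 22.5, 37.5, 75.0])
    max_mmhg: float = 75.0


class CalibrationConfig(_Strict):
    fit_flare: bool = True
    n_starts: int = 8
    volume_convention: str = "delta"


class RunConfig(_Strict):
    """Top-level configuration for all commands."""

    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    material: MaterialConfig = Field(default_factory=MaterialConfig)
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    out_dir: str = "sleevesim-out"
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not self.geometry.bougie_fr:
            raise ValueError("at least one bougie size is required")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(raw)

    def config_hash(self) -> str:
        """SHA-256 of the normalised configuration, for run logs."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
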