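"""Typed, schema-validated run configuration (YAML/JSON).

Unknown keys are rejected so typos never pass silently; every defaulted field
is logged with its value when a config file is loaded.
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "SimulateConfig",
    "VesselnessConfig",
    "RadiomicsSettings",
    "ModelingConfig",
    "RunConfig",
    "validate_config",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_StrictModel):
    n_train: int = Field(default=120, ge=2)
    n_validation: int = Field(default=120, ge=2)
    prevalence: float = Field(default=0.355, gt=0.0, lt=1.0)
    image_size: tuple[int, int] = (256, 256)
    vessel_count: int = Field(default=5, ge=0)
    vessel_width_range: tuple[int, int] = (1, 4)
    tumor_radius_range: tuple[float, float] = (10.0, 18.0)
    background_noise_sd: float = Field(default=4.0, ge=0.0)
    class_effect: float = Field(default=1.0, ge=0.0)


class VesselnessConfig(_StrictModel):
    scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    beta: float = Field(default=0.5, gt=0.0)
    c: float | None = None
    threshold: float | None = None
    min_size: int = Field(default=20, ge=0)
    closing_radius: int = Field(default=1, ge=0)
    max_hole_size: int = Field(default=64, ge=0)
    match_radius: float = Field(default=2.0, gt=0.0)

    @field_validator("scales")
    @classmethod
    def _increasing(cls, v):
        if any(b <= a for a, b in zip(v, v[1:])) or any(s <= 0 for s in v):
            raise ValueError("scales must be positive and strictly increasing")
        return v


class RadiomicsSettings(_StrictModel):
    bin_width: float = Field(default=25.0, gt=0.0)
    gldm_alpha: float = Field(default=0.0, ge=0.0)
    gldm_delta: int = Field(default=1, ge=1)
    dependence_base: int = Field(default=0, ge=0, le=1)
    wavelet: str = "coif1"


class ModelingConfig(_StrictModel):
    k: int = Field(default=5, ge=1)
    n_target: int = Field(default=10, ge=1)


class RunConfig(_StrictModel):
    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    vesselness: VesselnessConfig = VesselnessConfig()
    radiomics: RadiomicsSettings = RadiomicsSettings()
    modeling: ModelingConfig = ModelingConfig()


def validate_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    try:
        cfg = RunConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigError(f"invalid configuration {path}: {exc}") from exc
    for section, defaults in cfg.model_dump().items():
        logger.info("config %s = %r", section, defaults)
    return cfg
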