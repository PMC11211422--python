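"""Structured-text run configuration with schema validation.

Configs are YAML; the schema is strict (unknown keys are rejected, every
field has a default and documented units) and a canonical digest of the
resolved config is recorded for provenance.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class ConfigError(ValueError):
    """Raised when a configuration file violates the schema."""


class DomainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_lat: int = Field(6, ge=1, description="grid rows")
    n_lon: int = Field(6, ge=1, description="grid columns")
    land_fraction: float = Field(0.8, gt=0, le=1)
    seed: int = Field(0, ge=0)


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str = "SSP2-4.5"
    manure_on: bool = False
    co2_fertilization_on: bool = True
    perturbation: str = "none"
    noise_amplitude: float = Field(0.02, ge=0)
    trend_scale: float = 1.0


class PeriodsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    base: tuple[int, int] = (2000, 2020)
    eval: tuple[int, int] = (2079, 2099)

    @field_validator("base", "eval")
    @classmethod
    def _ordered(cls, v):
        if v[0] > v[1]:
            raise ValueError(f"period {v} must be (first, last)")
        return v


class RunConfig(BaseModel):
    """Full run configuration; see docs/methods.md for parameter units."""

    model_config = ConfigDict(extra="forbid")

    domain: DomainConfig = Field(default_factory=DomainConfig)
    scenarios: list[ScenarioConfig] = Field(
        default_factory=lambda: [ScenarioConfig()])
    start_year: int = 1950
    end_year: int = 2099
    dt_days: float = Field(30.0, gt=0, description="process step, days")
    seed: int = Field(0, ge=0)
    spin_up_drift_tolerance: float = Field(1e-3, gt=0)
    periods: PeriodsConfig = Field(default_factory=PeriodsConfig)
    parameter_overrides: dict[str, float] = Field(
        default_factory=dict,
        description="dotted keys, e.g. 'freshwater.q10': 2.2")
    output_dir: str = "results"

    def digest(self) -> str:
        canon = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError: re-raise with context
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)
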