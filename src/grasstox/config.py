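"""Validated run configuration for the command-line workflow.

Configuration files are plain YAML key-value documents; every field has a
default, so an empty (or absent) file is a valid configuration.  Paths are
resolved relative to the current working directory at run time.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["EngineSettings", "SweepSettings", "SynthSettings", "RunConfig",
           "load_config"]


class EngineSettings(BaseModel):
    conversion_rate: float = 0.1
    theta: float = 1.0
    kappa: float = Field(0.8, gt=0, le=1)
    k_below: float = Field(0.6, gt=0)
    k_form: dict[str, float] = {
        "rosette": 1.5, "semi-rosette": 1.0, "erect": 0.5
    }
    shoot_mass_fraction: float = Field(0.5, gt=0, lt=1)
    shoot_only_effect: bool = False

    def to_params(self):
        from .engine import EngineParams

        return EngineParams(
            conversion_rate=self.conversion_rate,
            theta=self.theta,
            kappa=self.kappa,
            k_form=dict(self.k_form),
            k_below=self.k_below,
            shoot_mass_fraction=self.shoot_mass_fraction,
            shoot_only_effect=self.shoot_only_effect,
        )


class SweepSettings(BaseModel):
    n_samples: int = Field(90, ge=1)
    reps: int = Field(10, ge=1)
    below_bounds: tuple[float, float] = (60.0, 120.0)
    above_bounds: tuple[float, float] = (50.0, 100.0)
    per_run: bool = False

    @field_validator("below_bounds", "above_bounds")
    @classmethod
    def _ordered(cls, v):
        if v[0] >= v[1]:
            raise ValueError(f"degenerate bounds {v}")
        return v


class SynthSettings(BaseModel):
    below: float = 90.0
    above: float = 75.0
    sigma: float = Field(0.15, ge=0)
    mono_reps: int = Field(4, ge=1)
    comm_reps: int = Field(3, ge=1)


class RunConfig(BaseModel):
    seed: int = 0
    trait_table: Optional[Path] = None  # None = packaged default
    dose_response_table: Optional[Path] = None
    aggregation_mode: str = "area"  # "area" | "weekly"
    fit_week: int = 4
    log_level: str = "INFO"
    engine: EngineSettings = EngineSettings()
    sweep: SweepSettings = SweepSettings()
    synth: SynthSettings = SynthSettings()

    @field_validator("aggregation_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("area", "weekly"):
            raise ValueError("aggregation_mode must be 'area' or 'weekly'")
        return v


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML configuration file; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
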