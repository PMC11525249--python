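"""Validated study configuration (YAML) for the simulation pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import List, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .simulate import COMPOSITION_PROPORTIONS, DEFAULT_REPLICATIONS

__all__ = ["FitSettings", "StudyConfig", "load_config"]


class FitSettings(BaseModel):
    """Estimation settings applied to every model fit of a study run."""

    model_config = ConfigDict(extra="forbid")

    algorithm: str = "mhrm"
    n_burnin: int = 150
    mh_draws: int = 5
    tol: float = 1e-3
    window: int = 3
    max_cycles: int = 2000
    quad_nodes: int = 21
    loglik_mc_draws: int = 1000


class StudyConfig(BaseModel):
    """Design factors, replication count, fit options, output paths, seed.

    Defaults reproduce the full factorial study design: 5 compositions x
    {6,12} items per trait x {500,1000,2000} persons x ERS present/absent x
    faking impact none/low/high, 100 replications per condition.
    """

    model_config = ConfigDict(extra="forbid")

    compositions: List[int] = Field(default=[1, 2, 3, 4, 5])
    items_per_trait: List[int] = Field(default=[6, 12])
    sample_sizes: List[int] = Field(default=[500, 1000, 2000])
    ers_levels: List[bool] = Field(default=[True, False])
    faking_impacts: List[str] = Field(default=["none", "low", "high"])
    replications: int = DEFAULT_REPLICATIONS
    weight_noise_scale: float = 0.5
    master_seed: int = 1
    out_dir: str = "study_results"
    fit: FitSettings = Field(default_factory=FitSettings)

    @field_validator("compositions")
    @classmethod
    def _check_compositions(cls, v: List[int]) -> List[int]:
        bad = [c for c in v if c not in COMPOSITION_PROPORTIONS]
        if bad:
            raise ValueError(f"unknown composition ids: {bad}")
        return v

    @field_validator("faking_impacts")
    @classmethod
    def _check_impacts(cls, v: List[str]) -> List[str]:
        bad = [f for f in v if f not in ("none", "low", "high")]
        if bad:
            raise ValueError(f"unknown faking impacts: {bad}")
        return v

    @field_validator("replications")
    @classmethod
    def _check_reps(cls, v: int) -> int:
        if v < 1:
            raise ValueError("replications must be positive")
        return v


def load_config(path: Union[str, Path]) -> StudyConfig:
    """Load and validate a YAML study configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return StudyConfig.model_validate(raw)
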