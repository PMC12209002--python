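"""Validated run configuration for the end-to-end pipeline."""

from __future__ import annotations

import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

log = logging.getLogger(__name__)


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_subjects: int = Field(default=22, ge=2)
    n_frames: int = Field(default=180, ge=10)
    n_parcels: int = Field(default=90, ge=4)
    n_states: int = Field(default=4, ge=1)
    tr_seconds: float = Field(default=2.0, gt=0)
    noise_sd: float = Field(default=0.8, ge=0)
    amplitude_mean: float = 1.0
    amplitude_sd: float = Field(default=0.25, ge=0)
    behavior_noise_sd: float = Field(default=0.6, ge=0)


class SelectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: str = "top_fraction"
    fraction: float = Field(default=0.15, gt=0, le=1)
    z_cut: float = 1.0
    polarity: str = "activation"


class ConsensusConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k_min: int = Field(default=2, ge=2)
    k_max: int = Field(default=8, ge=2)
    n_resamples: int = Field(default=100, ge=2)
    subsample_fraction: float = Field(default=0.8, gt=0, le=1)
    n_init: int = Field(default=1, ge=1)

    @model_validator(mode="after")
    def _ordered(self):
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        return self


class RunConfig(BaseModel):
    """Schema-validated configuration of one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    outdir: str = "runs/default"
    rng_seed: int = Field(default=0, ge=0)
    seed_network: str = "FPN"
    k_fixed: int | None = Field(default=None, ge=2)
    cohort: CohortConfig = CohortConfig()
    selection: SelectionConfig = SelectionConfig()
    consensus: ConsensusConfig = ConsensusConfig()
    kmeans_n_init: int = Field(default=20, ge=1)
    n_perm: int = Field(default=1000, ge=1)
    n_boot: int = Field(default=500, ge=1)
    models: list[str] = ["model1", "model2", "model3", "model4", "model5"]
    log_level: str = "INFO"

    def echo(self) -> None:
        """Log every effective setting, defaults included."""
        for line in yaml.safe_dump(self.model_dump(), sort_keys=True).splitlines():
            log.info("config: %s", line)


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig.model_validate(raw)
    cfg.echo()
    return cfg
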