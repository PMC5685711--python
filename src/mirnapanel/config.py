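"""Pipeline configuration: a single validated, hashable settings object.

Unknown keys are rejected (typos must not silently disable a stage) and
every threshold is range-checked.  The config's SHA-256 hash is stamped
into every output file so artifacts can be traced to the exact settings
and seed that produced them.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class CohortSettings(BaseModel):
    """Synthetic-cohort knobs exposed to the pipeline."""

    model_config = ConfigDict(extra="forbid")

    n_healthy: int = Field(63, ge=0)
    n_benign: int = Field(43, ge=0)
    n_early: int = Field(65, ge=0)
    n_advanced: int = Field(90, ge=0)
    n_mirnas: int = Field(40, ge=1)
    n_informative: int = Field(6, ge=0)
    n_allornone: int = Field(2, ge=0)
    effect_size: float = Field(0.9, description="log-scale group shift of informative markers")
    advanced_boost: float = Field(0.3, description="extra log-scale shift in advanced disease")
    noise_sd: float = Field(1.0, gt=0)
    nb_dispersion: float = Field(0.3, gt=0)
    subtype_effect: float = Field(1.0, description="log-scale subtype-specific shift")
    trial_fraction: float = Field(0.25, gt=0, le=1,
                                  description="trial-cohort size relative to development")


class PipelineConfig(BaseModel):
    """Settings for the end-to-end discovery pipeline."""

    model_config = ConfigDict(extra="forbid")

    outdir: Path = Path("results/pipeline")
    seed: int = Field(0, ge=0, lt=2**31)
    cohort: CohortSettings = CohortSettings()

    # screening thresholds
    top_k_method1: int = Field(10, ge=1)
    method1_alpha: float = Field(0.01, gt=0, le=1)
    method2_p_threshold: float = Field(0.05, gt=0, le=1)
    min_zero_healthy: int = Field(6, ge=1)
    validation_alpha: float = Field(0.05, gt=0, le=1)
    pool_size: int = Field(8, ge=1)

    # panel search
    n_reps: int = Field(1000, ge=1)
    auc_floor: float = Field(0.7, ge=0, le=1)
    top_k_models: int = Field(10, ge=1)
    include_ca125: bool = True
    swap_halves: bool = False

    # ROC / subtype settings
    ci_method: str = Field("delong", pattern="^(delong|bootstrap)$")
    cutoff_policy: str = Field("youden", pattern="^(youden|closest)$")
    run_subtypes: bool = True
    min_subtype_size: int = Field(8, ge=2)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(
            yaml.safe_load(yaml.safe_dump(self.model_dump(mode="json"))), sort_keys=True
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed}

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)
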