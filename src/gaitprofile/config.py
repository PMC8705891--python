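"""Pipeline configuration: a single validated, hashable document.

The configuration is a YAML/JSON-serialisable schema (pydantic model);
every pipeline run logs the fully resolved configuration and stamps each
artefact with its SHA-256 hash, so any output file can be traced to the
exact settings and seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

from .errors import ConfigurationError


class CohortConfig(BaseModel):
    """Synthetic study design (see :class:`gaitprofile.synth.SyntheticCohortSpec`)."""

    n_td: tuple[int, int, int] = (12, 10, 12)
    n_cp: int = 13
    responder_fraction: float = Field(0.5, ge=0.0, le=1.0)
    clinical_disagreement: float = Field(0.3, ge=0.0, le=1.0)
    operated_bilateral_fraction: float = Field(1.0, ge=0.0, le=1.0)
    trials_per_session: int = Field(1, ge=1)
    n_cycles: int = Field(3, ge=1)
    rate: float = Field(200.0, gt=0)
    surgical_effect: dict[str, float] = {"hip_rotation": -12.0, "knee_flexion": -6.0}
    non_responder_effect: dict[str, float] = {}
    sta_amplitude: dict[str, float] | None = None     # None -> documented defaults
    sta_tau: float = Field(0.15, gt=0)
    sta_harmonic_fraction: float = Field(0.5, ge=0.0, le=1.0)
    td_offset_sd: tuple[float, float] = (2.0, 1.0)
    cp_hip_rotation_offset: tuple[float, float] = (15.0, 3.0)
    cp_knee_flexion_offset: tuple[float, float] = (6.0, 2.0)
    session_jitter_sd: float = Field(0.2, ge=0.0)


class PipelineConfig(BaseModel):
    """Resolved settings of one end-to-end pipeline run."""

    outdir: str = "results/pipeline"
    seed: int = 0
    T: int = Field(101, ge=2, description="normalised-cycle grid points")
    mcid: float = Field(1.6, ge=0.0, description="GPS MCID, degrees")
    alpha_family: float = Field(0.05, gt=0.0, lt=1.0)
    n_comparisons: int = Field(9, ge=1)
    n_permutations: int = Field(1000, ge=100)
    engine: Literal["dk", "ik", "both"] = "both"
    age_group_boundaries: tuple[float, float] = (10.0, 16.0)
    subtalar_locked: bool = True
    cohort: CohortConfig = Field(default_factory=CohortConfig)

    @field_validator("age_group_boundaries")
    @classmethod
    def _ordered(cls, v):
        if not v[0] < v[1]:
            raise ValueError("age group boundaries must be increasing")
        return v

    @property
    def engines(self) -> list[str]:
        return ["dk", "ik"] if self.engine == "both" else [self.engine]

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(raw)
        except Exception as exc:
            raise ConfigurationError(f"invalid pipeline config {path}: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
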