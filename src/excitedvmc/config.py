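"""Validated run configuration (YAML-backed).

A run file has sections system/ansatz/sampler/training/evaluation/output.
Validation happens before any computation and errors name the offending
field; a stable hash of the parsed config is embedded in every artifact.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field, model_validator

from .io import config_hash

__all__ = ["RunConfig", "load_config"]


class SystemConfig(BaseModel):
    kind: Literal["model", "xyz"] = "model"
    model: Optional[Literal["harmonic"]] = "harmonic"
    omega: float = Field(1.0, gt=0)
    xyz: Optional[str] = None
    units: Optional[Literal["bohr", "angstrom"]] = None
    charge: int = 0
    multiplicity: int = Field(1, ge=1)

    @model_validator(mode="after")
    def _check(self):
        if self.kind == "xyz" and not self.xyz:
            raise ValueError("system.xyz: path required when kind is 'xyz'")
        return self


class AnsatzConfig(BaseModel):
    n_states: int = Field(2, ge=1)
    n_poly: int = Field(6, ge=1)
    width_mismatch: float = Field(1.0, gt=0)
    use_jastrow: bool = True
    use_backflow: bool = False
    hidden: tuple[int, ...] = (16, 16)
    max_determinants: int = Field(10, ge=1)
    fixed_spin: bool = False
    baseline_payload: Optional[str] = None  # JSON file with imported products
    seed: int = 0


class SamplerConfig(BaseModel):
    batch_size: int = Field(2000, ge=1)
    burn_in: int = Field(200, ge=0)
    decorrelation: int = Field(10, ge=1)


class TrainingSection(BaseModel):
    iterations: int = Field(2000, ge=1)
    alpha: float = Field(1.0, ge=0)
    ramp: Optional[tuple[float, float, int]] = None
    s_max: float = Field(0.999, gt=0.9, lt=1.0)
    clip_norm: float = Field(10.0, gt=0)
    learning_rate: Union[float, dict[str, float]] = 0.02
    checkpoint_every: int = Field(100, ge=1)
    ema_decay: float = Field(0.99, gt=0, lt=1)
    seed: int = 0


class EvaluationConfig(BaseModel):
    samples: int = Field(100_000, ge=100)
    thin: int = Field(10, ge=1)


class OutputConfig(BaseModel):
    directory: str = "runs/latest"


class RunConfig(BaseModel):
    system: SystemConfig = SystemConfig()
    ansatz: AnsatzConfig = AnsatzConfig()
    sampler: SamplerConfig = SamplerConfig()
    training: TrainingSection = TrainingSection()
    evaluation: EvaluationConfig = EvaluationConfig()
    output: OutputConfig = OutputConfig()

    @property
    def hash(self) -> str:
        return config_hash(self.model_dump())


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.model_validate(raw)
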