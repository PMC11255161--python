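"""Run configuration: validated YAML/JSON -> pydantic models."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .cohort import CohortConfig
from .errors import ConfigError
from .simplified import METHODS, TP_LABELS


class RunConfig(BaseModel):
    """Top-level configuration of a virtual study run.

    Unknown keys are rejected so typos fail fast.  All randomness flows
    from ``seed`` (which overrides the cohort seed when set).
    """

    model_config = ConfigDict(extra="forbid")

    cohort: CohortConfig = Field(default_factory=CohortConfig)
    methods: list[str] = ["RM", "SM1"]
    tp_labels: list[str] = list(TP_LABELS)
    seed: int | None = None
    out_dir: str = "results"
    denominator: str = "rm"  # percent-difference denominator: 'rm' or 'mean'
    n_cycles_total: int = Field(default=4, ge=1)

    @field_validator("methods")
    @classmethod
    def _methods_known(cls, v: list[str]) -> list[str]:
        unknown = [m for m in v if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; choose from {METHODS}")
        return v

    @field_validator("tp_labels")
    @classmethod
    def _tps_known(cls, v: list[str]) -> list[str]:
        unknown = [t for t in v if t not in TP_LABELS]
        if unknown:
            raise ValueError(f"unknown time-point labels {unknown}; choose from {TP_LABELS}")
        return v

    @field_validator("denominator")
    @classmethod
    def _denominator_known(cls, v: str) -> str:
        if v not in ("rm", "mean"):
            raise ValueError("denominator must be 'rm' or 'mean'")
        return v

    def effective_cohort(self) -> CohortConfig:
        if self.seed is None:
            return self.cohort
        return self.cohort.model_copy(update={"seed": self.seed})


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration file."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {p}: {exc}") from exc
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid configuration in {p}:\n{exc}") from exc
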