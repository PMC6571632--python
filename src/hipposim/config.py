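"""Validated run configuration with lossless YAML/JSON round-trips.

Every field defaults to the documented model defaults (the initial cell
parameter tables, 8 Hz theta, 0.5 ms cycles, CaMT = −68 mV, ReP = −80 mV),
so an empty config file reproduces the default experiment. Unknown keys
and constraint violations (e.g. a forgetting coefficient below 1) are
rejected with named validation errors.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .microcircuit import (
    LesionSchedule,
    NetworkConfig,
    build_default_network,
    build_lesion_schedule,
)
from .neuron_core import GlobalConstants
from .plasticity import PlasticityParams

__all__ = ["RunConfig", "load_config", "save_config", "config_hash", "make_network"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ConstantsConfig(_Strict):
    dt: float = Field(0.5, gt=0)
    ReP: float = -80.0
    refractory_ms: float = Field(1.5, gt=0)


class PlasticityConfig(_Strict):
    CaMT: float = -68.0
    FQ: float = Field(1.0, ge=1.0, description="forgetting coefficient, >= 1")
    decay_every: int = Field(2000, ge=1)


class CellOverride(_Strict):
    LSW: Optional[float] = Field(None, gt=0, le=1)
    EPSPd: Optional[float] = Field(None, gt=0)
    IPSPd: Optional[float] = Field(None, lt=0)
    spike_threshold: Optional[float] = None
    FQ: Optional[float] = Field(None, ge=1.0)


class ThresholdsConfig(_Strict):
    pyramidal: float = -55.0
    basket: float = -58.0
    olm: float = -58.0


class InputsConfig(_Strict):
    ec_rate_peak: float = Field(30.0, ge=0)
    dg_rate_peak: float = Field(16.0, ge=0)
    ms_rate_peak: float = Field(60.0, ge=0)
    theta_freq: float = Field(8.0, gt=0)
    ec2_phase: float = 0.0
    ec3_phase: float = float(np.pi)
    dg_phase: float = 0.0
    ms_phase: float = float(np.pi)
    n_ec_cells: int = Field(100, ge=1)
    n_dg_cells: int = Field(100, ge=1)
    fan_in: int = Field(2, ge=1)


class LesionConfig(_Strict):
    n_deletions: int | Literal["all", "none"] = "all"
    t_start: float = Field(500.0, ge=0)
    t_end: float = 7500.0
    order: Literal["listed", "random"] = "listed"


class AnalysisConfig(_Strict):
    final_window_ms: float = Field(1000.0, gt=0)
    nla_bins: int = Field(16, ge=2)


class RunConfig(_Strict):
    constants: ConstantsConfig = Field(default_factory=ConstantsConfig)
    plasticity: PlasticityConfig = Field(default_factory=PlasticityConfig)
    thresholds: ThresholdsConfig = Field(default_factory=ThresholdsConfig)
    cells: dict[str, CellOverride] = Field(default_factory=dict)
    inputs: InputsConfig = Field(default_factory=InputsConfig)
    lesion: LesionConfig = Field(default_factory=LesionConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    duration_ms: float = Field(10000.0, gt=0)
    record_every: int = Field(10, ge=1)
    seed: int = 0
    inhibitory_weight: float = Field(1.0, ge=0)
    output_dir: str = "results"

    @field_validator("cells")
    @classmethod
    def _known_cells(cls, v):
        from .microcircuit import DEFAULT_CELL_TABLE

        unknown = set(v) - set(DEFAULT_CELL_TABLE)
        if unknown:
            raise ValueError(f"override for unknown cell(s): {sorted(unknown)}")
        return v


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config; empty or missing -> defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    payload = config.model_dump(mode="json")
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def config_hash(config: RunConfig) -> str:
    """Short deterministic hash naming the exact configuration."""
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def make_network(config: RunConfig) -> NetworkConfig:
    """Instantiate the wired network described by a RunConfig."""
    overrides = {
        cid: {k: v for k, v in ov.model_dump().items() if v is not None}
        for cid, ov in config.cells.items()
    }
    net = build_default_network(
        overrides=overrides or None,
        thresholds=config.thresholds.model_dump(),
        fq=config.plasticity.FQ,
        fan_in=config.inputs.fan_in,
        n_ec_cells=config.inputs.n_ec_cells,
        n_dg_cells=config.inputs.n_dg_cells,
        inhibitory_weight=config.inhibitory_weight,
        seed=config.seed,
        constants=GlobalConstants(
            dt=config.constants.dt,
            ReP=config.constants.ReP,
            refractory_ms=config.constants.refractory_ms,
        ),
        plasticity=PlasticityParams(
            CaMT=config.plasticity.CaMT,
            ReP=config.constants.ReP,
            FQ=config.plasticity.FQ,
            decay_every=config.plasticity.decay_every,
        ),
    )
    net.input_settings.update(config.inputs.model_dump())
    return net


def make_lesion_schedule(
    config: RunConfig, network: NetworkConfig
) -> LesionSchedule:
    les = config.lesion
    n = les.n_deletions
    if n == "none":
        n = 0
    elif n == "all":
        n = None
    return build_lesion_schedule(
        network,
        n_deletions=n,
        t_start=les.t_start,
        t_end=les.t_end,
        order=les.order,
        seed=config.seed,
    )
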