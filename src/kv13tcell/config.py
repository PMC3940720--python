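"""Validated YAML configuration for schemes, protocols, cells and fits.

One human-readable document configures a run.  The schema is strict
(unknown keys are rejected with a message listing them) and every block
is optional with defaults equal to the shipped calibrated model; the
packaged ``data/default_config.yaml`` spells all of them out, including
the published rate-constant table verbatim.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .cell import CaParams, CellParams
from .errors import ConfigurationError
from .markov import KineticScheme, Kv13Model, RateConstants, SignConvention
from .protocols import (
    ChannelPopulation,
    activation_protocol,
    deactivation_protocol,
    recovery_protocol,
    ssi_protocol,
)

__all__ = [
    "RunConfig", "SchemeConfig", "RatesConfig", "ConventionConfig",
    "PopulationConfig", "ProtocolConfig", "CellConfig", "CaConfig", "FitConfig",
    "load_config", "default_config", "default_config_path",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SchemeConfig(_Strict):
    n_closed: int = 4
    closed_fwd_mults: Optional[list[float]] = None
    closed_bwd_mults: Optional[list[float]] = [3, 2, 3]

    def build(self) -> KineticScheme:
        return KineticScheme.linear(self.n_closed, self.closed_fwd_mults, self.closed_bwd_mults)


class RatesConfig(_Strict):
    a: float = 0.448
    b: float = 0.043
    c: float = 0.003
    d: float = 0.00008
    A: float = 280.035
    B: float = 1.648
    m: float = 27.530
    n: float = 17.528
    p: float = 174.961
    q: float = 1016.330

    def build(self) -> RateConstants:
        return RateConstants(**self.model_dump())


class ConventionConfig(_Strict):
    alpha: Literal[-1, 1] = 1
    beta: Literal[-1, 1] = -1
    eta: Literal[-1, 1] = 1
    phi: Literal[-1, 1] = 1

    def build(self) -> SignConvention:
        return SignConvention(**self.model_dump())


class PopulationConfig(_Strict):
    n_channels: int = 1500
    g_pS: float = 15.0
    e_rev_mV: float = -73.0

    def build(self) -> ChannelPopulation:
        return ChannelPopulation(**self.model_dump())


class ProtocolConfig(_Strict):
    kind: Literal["activation", "ssi", "deactivation", "recovery"] = "activation"
    v_rec_mV: float = -90.0
    intervals_ms: Optional[list[float]] = None

    def build(self):
        if self.kind == "activation":
            return activation_protocol()
        if self.kind == "ssi":
            return ssi_protocol()
        if self.kind == "deactivation":
            return deactivation_protocol()
        intervals = self.intervals_ms
        if intervals is None:
            # log-spaced 0.25-60 s grid, 10 points
            import numpy as np

            intervals = list(np.geomspace(250.0, 60_000.0, 10))
        return recovery_protocol(self.v_rec_mV, intervals)


class CellConfig(_Strict):
    cm_pF: float = 1.5
    v_rest_mV: float = -55.0
    g_task_nS: float = 0.13
    e_task_mV: float = -100.0
    g_crac_nS: float = 0.09
    e_crac_mV: float = 80.0
    g_ik_nS: float = 0.11
    e_ik_mV: float = -75.0
    kv_g_total_nS: float = 4.5
    i_inj_pA: float = 15.0
    duration_ms: float = 10_000.0

    def build(self, model: Kv13Model) -> CellParams:
        cp = CellParams(
            cm_pF=self.cm_pF,
            v_rest_mV=self.v_rest_mV,
            g_task_nS=self.g_task_nS,
            e_task_mV=self.e_task_mV,
            g_crac_nS=self.g_crac_nS,
            e_crac_mV=self.e_crac_mV,
            g_ik_nS=self.g_ik_nS,
            e_ik_mV=self.e_ik_mV,
            kv_model=model,
            i_inj_pA=self.i_inj_pA,
        )
        return cp.with_kv_conductance(self.kv_g_total_nS)


class CaConfig(_Strict):
    # calibrated transfer coefficient by default (see docs/methods.md);
    # the published table value is 0.006.
    e_trans: float = 0.003
    e_diff: float = 0.003
    kappa_global: float = 0.0682
    ik_k50_uM: float = 0.8
    ik_hill: float = 4.0

    def build(self) -> CaParams:
        return CaParams(**self.model_dump())


class FitConfig(_Strict):
    free: list[str] = Field(default_factory=lambda: ["a", "b", "m", "n"])
    n_particles: int = 20
    n_iterations: int = 200
    noise_sd_pA: float = 0.0


class RunConfig(_Strict):
    seed: int = 0
    dt_ms: float = 0.05
    output_dir: str = "out"
    scheme: SchemeConfig = Field(default_factory=SchemeConfig)
    rates: RatesConfig = Field(default_factory=RatesConfig)
    convention: ConventionConfig = Field(default_factory=ConventionConfig)
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    cell: CellConfig = Field(default_factory=CellConfig)
    ca: CaConfig = Field(default_factory=CaConfig)
    fit: FitConfig = Field(default_factory=FitConfig)

    def build_model(self) -> Kv13Model:
        return Kv13Model(
            scheme=self.scheme.build(),
            params=self.rates.build(),
            convention=self.convention.build(),
        )


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for item in err.errors():
        loc = ".".join(str(x) for x in item["loc"]) or "<root>"
        lines.append(f"  {loc}: {item['msg']}")
    return "invalid configuration:\n" + "\n".join(lines)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys anywhere in the document are schema errors; the raised
    :class:`ConfigurationError` lists every offending location.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as err:
        raise ConfigurationError(_format_validation_error(err)) from None


def default_config_path() -> Path:
    return Path(__file__).parent / "data" / "default_config.yaml"


def default_config() -> RunConfig:
    return load_config(default_config_path())
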