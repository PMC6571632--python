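"""NMDA-gated long-term potentiation with slow forgetting.

The memory rule works per dendritic compartment, independently of
postsynaptic spiking. Whenever a presynaptic action potential arrives and
the compartment's local potential S_k exceeds the magnesium-unblock
threshold CaMT (−68 mV), a scalar charge accumulator C grows by
``exp(10 * dV) − 1`` where dV is the depolarization of the NMDA register
head above rest, expressed in volts. The charge decays slowly: on a
configurable cadence, if C exceeds the forgetting coefficient FQ, FQ is
subtracted. The synaptic weight is scaled by the memory multiplier
``M = 1 + ln(C + 1) / 6`` (so M = 1 at C = 0), and a dimensionless
"time of memory" metric ``log10(C + 1)`` is reported alongside.

This gives the rule its signature asymmetry: a rapid weight increase per
gated event, and a very slow stepwise decrease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .neuron_core import REST_POTENTIAL_MV, CellState, ConfigurationError, SynapseClass

__all__ = [
    "CLOG",
    "CAMT_MV",
    "PlasticityParams",
    "LTPState",
    "MemoryValue",
    "ltp_gate",
    "update_charge",
    "memory_value",
    "effective_weight",
    "plasticity_step",
]

#: decimal-log conversion constant (ln 10 to 5 s.f.)
CLOG = 2.3026
#: NMDA Mg-block removal threshold (mV)
CAMT_MV = -68.0


@dataclass(frozen=True)
class PlasticityParams:
    """Parameters of the LTP/forgetting rule.

    decay_every is the forgetting cadence in 0.5 ms cycles; the default
    (2000 cycles = once per simulated second) makes the decrease very slow
    compared with the per-event rise.
    """

    CaMT: float = CAMT_MV
    ReP: float = REST_POTENTIAL_MV
    clog: float = CLOG
    FQ: float = 1.0
    decay_every: int = 2000

    def __post_init__(self) -> None:
        if self.CaMT <= self.ReP:
            raise ConfigurationError("CaMT must exceed the resting potential")
        if self.FQ < 1.0:
            raise ConfigurationError("FQ must be >= 1")
        if self.decay_every < 1:
            raise ConfigurationError("decay_every must be >= 1 cycle")


class MemoryValue(NamedTuple):
    multiplier: float  # weight multiplier, >= 1
    memory_time: float  # log10(C + 1), the reported "time of memory"


@dataclass
class LTPState:
    """Per-compartment memory state."""

    C: float = 0.0  # charge accumulator, dimensionless, >= 0
    M_mult: float = 1.0  # weight multiplier, >= 1
    memory_time: float = 0.0

    def refresh(self, clog: float = CLOG) -> None:
        self.M_mult, self.memory_time = memory_value(self.C, clog)


def ltp_gate(S_k: float, CaMT: float = CAMT_MV) -> bool:
    """True iff the local potential strictly exceeds the Mg-unblock
    threshold, permitting charge accumulation this cycle."""
    return S_k > CaMT


def update_charge(
    C: float,
    M_head: float,
    gated: bool,
    params: PlasticityParams,
    decay_due: bool = False,
) -> float:
    """One charge-accumulator update.

    If the gate is open, add ``exp(10 * dV) − 1`` with dV the NMDA-register
    head depolarization above rest in volts (mV / 1000); for small
    depolarizations the increment is ~10 dV. If a forgetting step is due
    and C exceeds FQ, subtract FQ. C is clamped at zero.
    """
    if C < 0:
        raise ValueError("charge accumulator must be >= 0")
    if gated:
        dv = (M_head - params.ReP) / 1000.0  # mV -> V
        C = C + math.expm1(10.0 * dv)
    if decay_due and C > params.FQ:
        C = C - params.FQ
    return max(C, 0.0)


def memory_value(C: float, clog: float = CLOG) -> MemoryValue:
    """Memory multiplier and "time of memory" for a charge level.

    multiplier = 1 + ln(C + 1)/6 (equals 1 at C = 0);
    memory_time = ln(C + 1)/clog, i.e. log10(C + 1).
    """
    if C < 0:
        raise ValueError("charge accumulator must be >= 0")
    lnc = math.log1p(C)
    return MemoryValue(1.0 + lnc / 6.0, lnc / clog)


def effective_weight(base_w: float, M_mult: float) -> float:
    """Potentiated synaptic weight; never below the base weight."""
    if M_mult < 1.0:
        raise ValueError("memory multiplier must be >= 1")
    return base_w * M_mult


def plasticity_step(
    cell: CellState,
    ltp_states: dict[int, LTPState],
    params: PlasticityParams,
    arrivals: set[int] | frozenset[int] = frozenset(),
    decay_due: bool = False,
) -> dict[int, LTPState]:
    """Advance the memory state of one cell by one 0.5 ms cycle.

    For every excitatory compartment with an arriving presynaptic spike
    this cycle, the gate is evaluated on the compartment's local potential
    S_k; when open, the charge grows from the NMDA register head. The
    scheduled forgetting step applies to all compartments regardless of
    arrivals. Multipliers are refreshed in place and mirrored into the
    cell's ``m_mult`` vector.
    """
    for k, st in ltp_states.items():
        comp = cell.compartments[k]
        excitatory = comp.synapse_class in (SynapseClass.AMPA, SynapseClass.NMDA)
        arrived = excitatory and not comp.deleted and k in arrivals
        gated = arrived and ltp_gate(cell.S[k], params.CaMT)
        m_head = comp.M.head if comp.M is not None else params.ReP
        st.C = update_charge(st.C, m_head, gated, params, decay_due=decay_due)
        st.refresh(params.clog)
        cell.m_mult[k] = st.M_mult
    return ltp_states


def memory_multiplier_array(C: np.ndarray) -> np.ndarray:
    """Vectorized multiplier ``1 + ln(C+1)/6`` used by the engine."""
    return 1.0 + np.log1p(C) / 6.0
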