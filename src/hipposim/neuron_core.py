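"""Shift-register compartmental neuron primitives.

Each model cell is a set of 16 compartments (axon, soma, dendrites). Every
compartment carries three shift registers — E (AMPA), M (NMDA) and I
(GABA-A) — whose boxes each represent 0.5 ms of future membrane potential
at that postsynaptic site. A presynaptic action potential stamps a
postsynaptic-potential (PSP) template into the relevant register; every
simulation cycle the head boxes are read, summed into a local potential
S_k, weighted by synaptic proximity, and compared with the cell's spike
threshold. On a spike all registers reset to the resting potential and the
cell is refractory for 1.5 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "REST_POTENTIAL_MV",
    "DT_MS",
    "GlobalConstants",
    "ShiftRegister",
    "PSPKind",
    "PSPTemplate",
    "SynapseClass",
    "Compartment",
    "CellParams",
    "CellState",
    "ConfigurationError",
    "make_register",
    "build_template",
    "inject_psp",
    "compartment_potential",
    "soma_drive",
    "fire_and_reset",
]

#: Resting membrane potential every register box starts from (mV).
REST_POTENTIAL_MV = -80.0
#: Duration of one register box / simulation cycle (ms).
DT_MS = 0.5
#: Number of compartments per cell.
N_COMPARTMENTS = 16


class ConfigurationError(ValueError):
    """Raised for invalid structural parameters (lengths, taus, wiring)."""


@dataclass(frozen=True)
class GlobalConstants:
    """Simulation-wide constants.

    Parameters
    ----------
    dt : float
        Cycle length in ms; one register box spans one cycle.
    ReP : float
        Resting potential in mV.
    refractory_ms : float
        Absolute refractory period after a spike; must be an integer
        multiple of ``dt``.
    spike_reset : bool
        Whether a spike resets every register box to ``ReP``.
    """

    dt: float = DT_MS
    ReP: float = REST_POTENTIAL_MV
    refractory_ms: float = 1.5
    spike_reset: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        n = self.refractory_ms / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "refractory period must be an integer multiple of dt"
            )

    @property
    def refractory_cycles(self) -> int:
        return int(round(self.refractory_ms / self.dt))


class ShiftRegister:
    """Future-potential buffer in 0.5 ms boxes.

    Box 0 is the current cycle. ``advance`` discards box 0 and appends a
    fresh resting-potential box at the tail, so with no injections the
    register is a fixed point at rest.
    """

    __slots__ = ("boxes", "rest")

    def __init__(self, length: int, rest: float = REST_POTENTIAL_MV):
        if length < 1:
            raise ConfigurationError("register length must be >= 1")
        self.rest = float(rest)
        self.boxes = np.full(int(length), self.rest, dtype=float)

    def __len__(self) -> int:
        return self.boxes.size

    @property
    def head(self) -> float:
        """Potential of the current cycle's box (mV)."""
        return float(self.boxes[0])

    def advance(self) -> None:
        self.boxes[:-1] = self.boxes[1:]
        self.boxes[-1] = self.rest

    def reset(self) -> None:
        self.boxes[:] = self.rest

    def deviations(self) -> np.ndarray:
        """Box values relative to rest (mV)."""
        return self.boxes - self.rest


def make_register(length: int, rest: float = REST_POTENTIAL_MV) -> ShiftRegister:
    """Create a register with every box at the resting potential."""
    return ShiftRegister(length, rest)


class PSPKind(str, Enum):
    EXCITATORY = "excitatory"
    INHIBITORY = "inhibitory"


class SynapseClass(str, Enum):
    AMPA = "AMPA"
    NMDA = "NMDA"
    GABA_A = "GABA_A"
    NONE = "none"


@dataclass(frozen=True)
class PSPTemplate:
    """Discrete PSP time course sampled at ``dt``.

    ``values`` are deviations from rest (mV); the extremum equals ``peak``
    exactly. A dual-exponential (alpha-like) shape is used: the tables of
    cell parameters state only the PSP peak amplitudes (EPSPd / IPSPd), so
    the kinetics are free parameters with AMPA/GABA-A defaulting to fast
    (2 ms rise, 6 ms decay) and NMDA to slow (5 ms rise, 25 ms decay).
    """

    kind: PSPKind
    peak: float
    rise_tau: float
    decay_tau: float
    values: np.ndarray = field(repr=False)

    @property
    def support(self) -> int:
        """Number of boxes with non-negligible amplitude."""
        return int(self.values.size)


def build_template(
    kind: PSPKind | str,
    peak: float,
    rise_tau: float,
    decay_tau: float,
    dt: float = DT_MS,
    cutoff: float = 1e-3,
) -> PSPTemplate:
    """Build a dual-exponential PSP template with the requested peak.

    The continuous shape ``exp(-t/decay) - exp(-t/rise)`` is sampled at
    ``dt`` and rescaled so the sampled extremum equals ``peak`` exactly.
    The template is truncated once the amplitude falls below
    ``cutoff * |peak|`` after the peak. A zero peak yields a minimal
    all-zero template.
    """
    kind = PSPKind(kind)
    if rise_tau <= 0 or decay_tau <= 0:
        raise ConfigurationError("PSP time constants must be positive")
    if decay_tau <= rise_tau:
        raise ConfigurationError("decay_tau must exceed rise_tau")
    if peak > 0 and kind is PSPKind.INHIBITORY:
        raise ConfigurationError("inhibitory template requires peak < 0")
    if peak < 0 and kind is PSPKind.EXCITATORY:
        raise ConfigurationError("excitatory template requires peak > 0")

    if peak == 0:
        return PSPTemplate(kind, 0.0, rise_tau, decay_tau, np.zeros(1))

    # sample long enough to capture rise + several decay constants
    t = np.arange(0.0, rise_tau + 8.0 * decay_tau, dt)
    shape = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    shape *= peak / shape.max()
    # truncate negligible tail (after the peak)
    above = np.nonzero(np.abs(shape) >= abs(peak) * cutoff)[0]
    values = shape[: above[-1] + 1]
    return PSPTemplate(kind, float(peak), rise_tau, decay_tau, values)


def inject_psp(
    register: ShiftRegister,
    template: PSPTemplate,
    weight: float = 1.0,
    delay: int = 0,
) -> ShiftRegister:
    """Add ``weight * template`` into the register starting ``delay`` boxes
    ahead of the head. Contributions from overlapping events are additive.
    A template running past the register tail is truncated with a warning.
    """
    if weight < 0:
        raise ConfigurationError("injection weight must be >= 0")
    if delay < 0:
        raise ConfigurationError("injection delay must be >= 0")
    if weight == 0.0:
        return register
    n = register.boxes.size
    span = min(template.values.size, n - delay)
    if span < template.values.size:
        warnings.warn(
            "PSP template truncated at register tail "
            f"({template.values.size - max(span, 0)} boxes lost)",
            RuntimeWarning,
            stacklevel=2,
        )
    if span > 0:
        register.boxes[delay : delay + span] += weight * template.values[:span]
    return register


@dataclass
class CellParams:
    """Per-cell-type parameters.

    LSW ("low significant weight") is the weight of the most distal
    dendritic input; weights interpolate linearly from 1.0 at the most
    proximal dendritic compartment down to LSW distally. EPSPd / IPSPd are
    the PSP peak amplitudes in mV. FQ is the forgetting coefficient of the
    memory rule (>= 1).
    """

    cell_type: str  # pyramidal | basket | olm
    LSW: float
    EPSPd: float
    IPSPd: float
    spike_threshold: float
    FQ: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.LSW <= 1.0):
            raise ConfigurationError("LSW must lie in (0, 1]")
        if self.FQ < 1.0:
            raise ConfigurationError("FQ must be >= 1 (forgetting coefficient not below 1)")
        if self.EPSPd <= 0:
            raise ConfigurationError("EPSPd must be positive")
        if self.IPSPd >= 0:
            raise ConfigurationError("IPSPd must be negative")


@dataclass
class Compartment:
    """One of a cell's 16 compartments with its E/M/I registers."""

    index: int
    role: str  # soma | axon | apical-dendrite | basal-dendrite
    synapse_class: SynapseClass = SynapseClass.NONE
    base_weight: float = 0.0
    E: Optional[ShiftRegister] = None
    M: Optional[ShiftRegister] = None
    I: Optional[ShiftRegister] = None
    deleted: bool = False

    def make_registers(self, length: int, rest: float = REST_POTENTIAL_MV) -> None:
        self.E = make_register(length, rest)
        self.M = make_register(length, rest)
        self.I = make_register(length, rest)


@dataclass
class CellState:
    """Mutable runtime state of one cell."""

    params: CellParams
    compartments: list[Compartment]
    constants: GlobalConstants = field(default_factory=GlobalConstants)
    S: np.ndarray = field(default=None)  # accumulated local potentials, mV
    m_mult: np.ndarray = field(default=None)  # LTP weight multipliers
    refractory_cycles_left: int = 0
    spike_times: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.compartments)
        if self.S is None:
            self.S = np.full(n, self.constants.ReP, dtype=float)
        if self.m_mult is None:
            self.m_mult = np.ones(n, dtype=float)

    @property
    def is_refractory(self) -> bool:
        return self.refractory_cycles_left > 0


def compartment_potential(comp: Compartment, ReP: float = REST_POTENTIAL_MV) -> float:
    """Accumulated local potential S_k of one compartment (mV).

    Head-box deviations of the three registers superpose on the resting
    potential: ``S_k = ReP + (E0 - ReP) + (M0 - ReP) + (I0 - ReP)``.
    """
    s = ReP
    for reg in (comp.E, comp.M, comp.I):
        if reg is not None:
            s += reg.head - ReP
    return s


def soma_drive(cell: CellState) -> float:
    """Weighted somatic drive of the cell (mV).

    ``drive = ReP + sum_k w_eff(k) * (S_k - ReP)`` where the effective
    weight is the compartment's base weight (largest proximally) times its
    LTP memory multiplier.
    """
    ReP = cell.constants.ReP
    drive = ReP
    for comp in cell.compartments:
        if comp.base_weight == 0.0:
            continue
        w_eff = comp.base_weight * cell.m_mult[comp.index]
        drive += w_eff * (cell.S[comp.index] - ReP)
    return drive


def fire_and_reset(cell: CellState, t_ms: float, drive: float) -> bool:
    """Spike if the drive crosses threshold and the cell is excitable.

    On a spike the time is recorded, every register box resets to the
    resting potential and the cell becomes refractory for
    ``refractory_cycles`` cycles. Returns True iff a spike occurred.
    """
    if cell.is_refractory or drive <= cell.params.spike_threshold:
        return False
    cell.spike_times.append(t_ms)
    if cell.constants.spike_reset:
        for comp in cell.compartments:
            for reg in (comp.E, comp.M, comp.I):
                if reg is not None:
                    reg.reset()
    cell.refractory_cycles_left = cell.constants.refractory_cycles
    return True
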