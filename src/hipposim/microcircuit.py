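"""CA3-CA1 microcircuit wiring and the synaptic-deletion lesion protocol.

The network comprises 14 cells: four CA3 pyramidal cells (P5-P8), two CA3
basket cells (B3, B4), one CA3 O-LM cell (OLM2), four CA1 pyramidal cells
(P1-P4), two CA1 basket cells (B1, B2) and one CA1 O-LM cell (OLM1).
External drive comes from EC2 (to CA3 PCs and BCs, distal apical), EC3 (to
CA1 PCs and BCs, distal lacunosum-moleculare), dentate mossy fibers
relayed through the mossy cell onto CA3 PC medium dendrites, and the
medial-septum theta pacemaker onto basket and O-LM somas.

Every pyramidal cell carries 13 excitatory synapses — 4 distal (EC), 5
medium (mossy or Schaffer, AMPA+NMDA) and 4 proximal (recurrent) — for
8 x 13 = 104 excitatory synapses over P1-P8.

Alzheimer-type degradation is modeled by switching off, one after the
other, the EC2 synapses on CA3 pyramidal cells and basket cells and the
mossy-fiber synapses on CA3 pyramidal cells; CA1 wiring is never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .neuron_core import (
    CellParams,
    ConfigurationError,
    GlobalConstants,
    SynapseClass,
)
from .plasticity import PlasticityParams

__all__ = [
    "AXON",
    "SOMA",
    "PROXIMAL",
    "MEDIUM",
    "DISTAL",
    "BASAL",
    "CellSpec",
    "Connection",
    "NetworkConfig",
    "LesionSchedule",
    "LesionEvent",
    "DEFAULT_CELL_TABLE",
    "build_default_network",
    "weight_gradient",
    "build_lesion_schedule",
    "apply_lesion",
]

# ---------------------------------------------------------------------------
# Compartment layout (identical 16-slot template for every cell)
# ---------------------------------------------------------------------------
N_COMPARTMENTS_PER_CELL = 16
AXON = 0
SOMA = 1
PROXIMAL = (2, 3, 4, 5)  # recurrent excitation (pyramidal cells)
MEDIUM = (6, 7, 8, 9, 10)  # mossy / Schaffer AMPA+NMDA (pyramidal cells)
DISTAL = (11, 12, 13, 14)  # EC input, apical lacunosum-moleculare
BASAL = 15  # basal dendrite (PC drive onto O-LM cells)

#: dendritic span used for the proximity weight gradient
_DENDRITE_FIRST, _DENDRITE_LAST = PROXIMAL[0], DISTAL[-1]

# Default spike thresholds (mV); the tables of initial parameters give no
# thresholds, so pyramidal cells default to -55 mV and the faster-spiking
# interneurons to -58 mV, all configurable.
PYR_THRESHOLD = -55.0
INTERNEURON_THRESHOLD = -58.0

#: Initial cell parameters: (cell_type, LSW, EPSPd mV, IPSPd mV)
DEFAULT_CELL_TABLE: dict[str, tuple[str, float, float, float]] = {
    # CA1
    "P1": ("pyramidal", 0.2, 4.5, -6.0),
    "P2": ("pyramidal", 0.2, 4.5, -6.0),
    "P3": ("pyramidal", 0.2, 4.5, -6.0),
    "P4": ("pyramidal", 0.2, 4.5, -6.0),
    "B1": ("basket", 1.0, 4.0, -4.5),
    "B2": ("basket", 1.0, 4.0, -5.5),
    "OLM1": ("olm", 0.6, 4.0, -4.0),
    # CA3
    "P5": ("pyramidal", 0.6, 4.5, -6.0),
    "P6": ("pyramidal", 0.6, 4.5, -6.0),
    "P7": ("pyramidal", 0.6, 4.5, -6.0),
    "P8": ("pyramidal", 0.6, 4.5, -6.0),
    "B3": ("basket", 1.0, 4.0, -4.5),
    "B4": ("basket", 1.0, 4.0, -5.5),
    "OLM2": ("olm", 0.6, 4.0, -4.0),
}

CA1_CELLS = ("P1", "P2", "P3", "P4", "B1", "B2", "OLM1")
CA3_CELLS = ("P5", "P6", "P7", "P8", "B3", "B4", "OLM2")
CA1_PCS = ("P1", "P2", "P3", "P4")
CA3_PCS = ("P5", "P6", "P7", "P8")


@dataclass(frozen=True)
class CellSpec:
    id: str
    region: str  # CA1 | CA3
    params: CellParams


@dataclass
class Connection:
    """A synapse (or bundle of co-localized receptors) on one compartment.

    ``source`` is a cell id (intra-network) or an input-population id
    (EC2, EC3, DG, MS); input-sourced connections also carry the indices
    of the population cells funneled onto this synapse.
    """

    id: str
    source: str
    target: str
    target_compartment: int
    synapse_class: SynapseClass
    receptors: tuple[str, ...]  # subset of ("AMPA", "NMDA", "GABA_A")
    base_weight: float
    delay_boxes: int = 1
    lesionable: bool = False
    deleted: bool = False
    source_cells: tuple[int, ...] = ()

    @property
    def is_excitatory(self) -> bool:
        return "AMPA" in self.receptors or "NMDA" in self.receptors


@dataclass
class NetworkConfig:
    """Complete wiring + parameters of the 14-cell microcircuit."""

    cells: dict[str, CellSpec]
    connections: list[Connection]
    constants: GlobalConstants = field(default_factory=GlobalConstants)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    input_settings: dict = field(default_factory=dict)

    def connection(self, conn_id: str) -> Connection:
        for c in self.connections:
            if c.id == conn_id:
                return c
        raise KeyError(conn_id)

    def lesionable_connections(self) -> list[Connection]:
        return [c for c in self.connections if c.lesionable]

    def n_excitatory_pc_synapses(self) -> int:
        pcs = set(CA1_PCS) | set(CA3_PCS)
        return sum(
            1 for c in self.connections if c.target in pcs and c.is_excitatory
        )


@dataclass(frozen=True)
class LesionEvent:
    time_ms: float
    connection_id: str


@dataclass
class LesionSchedule:
    """Ordered deletion times for CA3 afferent synapses."""

    events: list[LesionEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.time_ms for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ConfigurationError("lesion event times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.events)

    def cumulative_deletions(self, t_ms: np.ndarray) -> np.ndarray:
        """Deleted-synapse count at each requested time (step function)."""
        times = np.array([e.time_ms for e in self.events])
        return np.searchsorted(times, np.asarray(t_ms, dtype=float), side="right")


def weight_gradient(
    k: int | float,
    LSW: float,
    k_proximal: int | float = _DENDRITE_FIRST,
    k_distal: int | float = _DENDRITE_LAST,
) -> float:
    """Synaptic base weight by dendritic position.

    Linear interpolation from 1.0 at the most proximal dendritic
    compartment down to LSW at the most distal, encoding the positive
    correlation between weight and proximity to the cell body.
    """
    if not (k_proximal <= k <= k_distal):
        raise ConfigurationError(
            f"compartment {k} outside dendritic span [{k_proximal}, {k_distal}]"
        )
    frac = (k - k_proximal) / (k_distal - k_proximal) if k_distal > k_proximal else 0.0
    return 1.0 + (LSW - 1.0) * frac


def _cell_params(
    cell_id: str,
    thresholds: dict[str, float],
    fq: dict[str, float] | float,
    overrides: dict[str, dict] | None,
) -> CellParams:
    cell_type, lsw, epspd, ipspd = DEFAULT_CELL_TABLE[cell_id]
    thr = thresholds.get(cell_type, PYR_THRESHOLD)
    fq_val = fq if isinstance(fq, (int, float)) else fq.get(cell_id, 1.0)
    kw = dict(
        cell_type=cell_type,
        LSW=lsw,
        EPSPd=epspd,
        IPSPd=ipspd,
        spike_threshold=thr,
        FQ=float(fq_val),
    )
    if overrides and cell_id in overrides:
        unknown = set(overrides[cell_id]) - set(kw)
        if unknown:
            raise ConfigurationError(
                f"unknown cell-parameter override(s) for {cell_id}: {sorted(unknown)}"
            )
        kw.update(overrides[cell_id])
    return CellParams(**kw)


def _assign_sources(rng: np.random.Generator, n_pool: int, fan_in: int) -> tuple[int, ...]:
    fan_in = min(fan_in, n_pool)
    return tuple(int(i) for i in rng.choice(n_pool, size=fan_in, replace=False))


def build_default_network(
    overrides: dict[str, dict] | None = None,
    *,
    thresholds: dict[str, float] | None = None,
    fq: dict[str, float] | float = 1.0,
    fan_in: int = 2,
    n_ec_cells: int = 100,
    n_dg_cells: int = 100,
    delay_boxes: int = 1,
    inhibitory_weight: float = 1.0,
    seed: int | None = None,
    constants: GlobalConstants | None = None,
    plasticity: PlasticityParams | None = None,
) -> NetworkConfig:
    """Construct the default 14-cell CA3-CA1 network.

    Parameters
    ----------
    overrides : mapping cell id -> {field: value}
        Per-cell parameter overrides (e.g. ``{"P1": {"LSW": 0.5}}``).
    fan_in : int
        Number of distinct input-population cells funneled onto each
        input-driven synapse (seeded random assignment).
    seed : int
        Seeds the input-cell-to-synapse assignment only.
    """
    thresholds = dict(thresholds or {})
    thresholds.setdefault("pyramidal", PYR_THRESHOLD)
    thresholds.setdefault("basket", INTERNEURON_THRESHOLD)
    thresholds.setdefault("olm", INTERNEURON_THRESHOLD)
    if overrides:
        unknown = set(overrides) - set(DEFAULT_CELL_TABLE)
        if unknown:
            raise ConfigurationError(f"override for unknown cell(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    cells = {
        cid: CellSpec(
            id=cid,
            region="CA1" if cid in CA1_CELLS else "CA3",
            params=_cell_params(cid, thresholds, fq, overrides),
        )
        for cid in CA1_CELLS + CA3_CELLS
    }

    conns: list[Connection] = []

    def add(
        source: str,
        target: str,
        comp: int,
        receptors: tuple[str, ...],
        *,
        lesionable: bool = False,
        weight: float | None = None,
        pool: int = 0,
    ) -> None:
        cls = SynapseClass(receptors[0] if receptors[0] != "GABA_A" else "GABA_A")
        if weight is None:
            lsw = cells[target].params.LSW
            weight = weight_gradient(comp, lsw)
        src_cells: tuple[int, ...] = ()
        if pool:
            src_cells = _assign_sources(rng, pool, fan_in)
        conns.append(
            Connection(
                id=f"{source}->{target}:{comp}",
                source=source,
                target=target,
                target_compartment=comp,
                synapse_class=cls,
                receptors=receptors,
                base_weight=float(weight),
                delay_boxes=delay_boxes,
                lesionable=lesionable,
                source_cells=src_cells,
            )
        )

    # ----- CA3 ------------------------------------------------------------
    for pc in CA3_PCS:
        for k in DISTAL:  # EC2 -> distal apical (AMPA), lesionable
            add("EC2", pc, k, ("AMPA",), lesionable=True, pool=n_ec_cells)
        for k in MEDIUM:  # DG mossy fibers via mossy-cell relay, lesionable
            add("DG", pc, k, ("AMPA", "NMDA"), lesionable=True, pool=n_dg_cells)
        others = [p for p in CA3_PCS if p != pc]
        for j, k in enumerate(PROXIMAL):  # recurrent CA3 excitation
            add(others[j % len(others)], pc, k, ("AMPA",))
    for bc in ("B3", "B4"):
        for k in DISTAL:  # EC2 -> basket distal (lesionable)
            add("EC2", bc, k, ("AMPA",), lesionable=True, pool=n_ec_cells)
        for j, pc in enumerate(CA3_PCS):  # feedback PC -> BC excitation
            add(pc, bc, MEDIUM[j], ("AMPA",))
        add("MS", bc, SOMA, ("GABA_A",), weight=inhibitory_weight, pool=6)
    add("B3", "B4", SOMA, ("GABA_A",), weight=inhibitory_weight)
    add("B4", "B3", SOMA, ("GABA_A",), weight=inhibitory_weight)
    for pc in CA3_PCS:
        add("B3", pc, SOMA, ("GABA_A",), weight=inhibitory_weight)
        add("B4", pc, SOMA, ("GABA_A",), weight=inhibitory_weight)
    for j, pc in enumerate(CA3_PCS):  # PC basal-axon drive onto O-LM
        add(pc, "OLM2", PROXIMAL[j], ("AMPA",))
    add("MS", "OLM2", SOMA, ("GABA_A",), weight=inhibitory_weight, pool=6)
    for pc in CA3_PCS:  # O-LM dendritic inhibition of distal apical tufts
        for k in DISTAL:
            add("OLM2", pc, k, ("GABA_A",), weight=inhibitory_weight)

    # ----- CA1 ------------------------------------------------------------
    schaffer = list(CA3_PCS)
    for pc in CA1_PCS:
        for k in DISTAL:  # EC3 -> distal LM (AMPA), never lesioned
            add("EC3", pc, k, ("AMPA",), pool=n_ec_cells)
        for j, k in enumerate(MEDIUM):  # Schaffer collaterals, AMPA+NMDA
            add(schaffer[j % len(schaffer)], pc, k, ("AMPA", "NMDA"))
        others = [p for p in CA1_PCS if p != pc]
        for j, k in enumerate(PROXIMAL):  # recurrent CA1 excitation
            add(others[j % len(others)], pc, k, ("AMPA",))
    for bc in ("B1", "B2"):
        for k in DISTAL:
            add("EC3", bc, k, ("AMPA",), pool=n_ec_cells)
        for j, pc in enumerate(CA1_PCS):
            add(pc, bc, MEDIUM[j], ("AMPA",))
        add("MS", bc, SOMA, ("GABA_A",), weight=inhibitory_weight, pool=6)
    add("B1", "B2", SOMA, ("GABA_A",), weight=inhibitory_weight)
    add("B2", "B1", SOMA, ("GABA_A",), weight=inhibitory_weight)
    for pc in CA1_PCS:
        add("B1", pc, SOMA, ("GABA_A",), weight=inhibitory_weight)
        add("B2", pc, SOMA, ("GABA_A",), weight=inhibitory_weight)
    for j, pc in enumerate(CA1_PCS):
        add(pc, "OLM1", PROXIMAL[j], ("AMPA",))
    add("MS", "OLM1", SOMA, ("GABA_A",), weight=inhibitory_weight, pool=6)
    for pc in CA1_PCS:
        for k in DISTAL:
            add("OLM1", pc, k, ("GABA_A",), weight=inhibitory_weight)

    net = NetworkConfig(
        cells=cells,
        connections=conns,
        constants=constants or GlobalConstants(),
        plasticity=plasticity or PlasticityParams(),
        input_settings={
            "fan_in": fan_in,
            "n_ec_cells": n_ec_cells,
            "n_dg_cells": n_dg_cells,
            "seed": seed,
        },
    )
    assert len(net.cells) == 14
    assert net.n_excitatory_pc_synapses() == 104
    return net


def instantiate_cells(
    config: NetworkConfig, register_length: int = 120
) -> dict[str, "CellState"]:
    """Materialize every cell as a 16-compartment ``CellState``.

    Compartment roles, synapse classes and base weights are derived from
    the wiring; each compartment carries freshly initialized E/M/I
    registers. Useful for object-level inspection and tests; the engine
    packs the same state into arrays.
    """
    from .neuron_core import CellState, Compartment

    cells: dict[str, CellState] = {}
    for cid, spec in config.cells.items():
        comps = []
        for k in range(N_COMPARTMENTS_PER_CELL):
            if k == AXON:
                role = "axon"
            elif k == SOMA:
                role = "soma"
            elif k == BASAL or k in PROXIMAL:
                role = "basal-dendrite" if k == BASAL else "apical-dendrite"
            else:
                role = "apical-dendrite"
            comp = Compartment(index=k, role=role)
            comp.make_registers(register_length, config.constants.ReP)
            comps.append(comp)
        comps[SOMA].base_weight = 1.0
        cells[cid] = CellState(
            params=spec.params, compartments=comps, constants=config.constants
        )
    for c in config.connections:
        comp = cells[c.target].compartments[c.target_compartment]
        comp.synapse_class = c.synapse_class
        comp.base_weight = max(comp.base_weight, c.base_weight)
        comp.deleted = c.deleted
    return cells


def build_lesion_schedule(
    config: NetworkConfig,
    n_deletions: int | None = None,
    t_start: float = 500.0,
    t_end: float = 7500.0,
    order: str = "listed",
    seed: int | None = None,
) -> LesionSchedule:
    """Schedule progressive CA3-afferent deletions.

    ``n_deletions`` events (default: all lesionable connections) are
    placed at uniformly spaced times in [t_start, t_end] inclusive. Order
    is either "listed" (EC2->PC, then EC2->BC, then mossy, by
    construction order) or "random" (seeded shuffle).
    """
    lesionable = config.lesionable_connections()
    if n_deletions is None:
        n_deletions = len(lesionable)
    if n_deletions > len(lesionable):
        raise ConfigurationError(
            f"n_deletions={n_deletions} exceeds the {len(lesionable)} "
            "lesionable connections"
        )
    if n_deletions == 0:
        return LesionSchedule([])
    ids = [c.id for c in lesionable]
    if order == "random":
        rng = np.random.default_rng(seed)
        ids = [ids[i] for i in rng.permutation(len(ids))]
    elif order != "listed":
        raise ConfigurationError("order must be 'listed' or 'random'")
    times = (
        np.linspace(t_start, t_end, n_deletions)
        if n_deletions > 1
        else np.array([t_start])
    )
    return LesionSchedule(
        [LesionEvent(float(t), cid) for t, cid in zip(times, ids[:n_deletions])]
    )


def apply_lesion(
    config: NetworkConfig, schedule: LesionSchedule, t_ms: float
) -> int:
    """Mark every connection whose deletion time has passed as deleted.

    Deletion is irreversible; deleted connections inject no PSPs and
    accumulate no charge. Returns the cumulative number of deletions.
    """
    count = 0
    for ev in schedule.events:
        if ev.time_ms <= t_ms:
            config.connection(ev.connection_id).deleted = True
            count += 1
    return count
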