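"""Stage-synchronous 0.5 ms state-updating loop over the whole network.

Each cycle: (1) apply due lesions; (2) deliver input and intra-network
spikes into the E/M/I registers; (3) read register heads into local
potentials S_k and weighted somatic drives; (4) run the LTP memory rule;
(5) threshold, spike and reset; (6) advance all registers. All cells see
the previous cycle's spikes (stage-synchronous update), so the iteration
order over cells is irrelevant. The whole run is deterministic given the
seed.

Internally the registers of all 14 cells are packed into three
(n_cells, 16, L) circular arrays for speed; the semantics are exactly
those of the per-compartment ``ShiftRegister`` objects.
"""

from __future__ import annotations

import copy
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inputs import InputPopulation, InputSpikeTrains, generate_theta_population
from .microcircuit import (
    LesionSchedule,
    NetworkConfig,
    N_COMPARTMENTS_PER_CELL,
)
from .neuron_core import ConfigurationError, build_template
from .plasticity import memory_multiplier_array

__all__ = ["SimulationResult", "run", "step_count"]

# default theta-drive settings for the four external sources; rates are the
# free calibration parameters of the model (documented in the methods note)
DEFAULT_INPUT_RATES = {
    "ec_rate_peak": 30.0,  # Hz per EC cell at the theta maximum
    "dg_rate_peak": 16.0,  # Hz per DG granule-cell source
    "ms_rate_peak": 60.0,  # Hz per MS pacemaker cell
    "ec2_phase": 0.0,
    "ec3_phase": np.pi,
    "dg_phase": 0.0,
    "ms_phase": np.pi,
    "theta_freq": 8.0,
}

# PSP kinetics per receptor class (ms); peaks come from the per-cell tables
PSP_TAUS = {
    "AMPA": (2.0, 6.0),
    "NMDA": (5.0, 25.0),
    "GABA_A": (2.0, 6.0),
}


@dataclass
class SimulationResult:
    """Everything a 10 s run produces, on a shared time base."""

    spike_trains: dict[str, np.ndarray]
    trace_time_ms: np.ndarray
    memory_traces: dict[str, np.ndarray]  # per-PC mean memory multiplier
    deletion_series: np.ndarray  # cumulative deleted synapses at trace times
    duration: float
    seed: int | None
    dt: float
    config_echo: dict = field(default_factory=dict)
    input_trains: dict[str, InputSpikeTrains] = field(default_factory=dict, repr=False)
    drive_traces: dict[str, np.ndarray] | None = field(default=None, repr=False)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.spike_trains)

    def spike_count(self, cell_id: str) -> int:
        return int(self.spike_trains[cell_id].size)

    def total_spikes(self, cells: list[str] | None = None) -> int:
        cells = cells or self.cell_ids
        return sum(self.spike_count(c) for c in cells)

    def to_spikes_frame(self) -> pd.DataFrame:
        rows = [
            (cid, t) for cid, train in self.spike_trains.items() for t in train
        ]
        return pd.DataFrame(rows, columns=["cell_id", "t_ms"])

    def to_memory_frame(self) -> pd.DataFrame:
        frames = []
        for cid, trace in self.memory_traces.items():
            frames.append(
                pd.DataFrame(
                    {"t_ms": self.trace_time_ms, "cell_id": cid, "mean_M_mult": trace}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def write_outputs(self, out_dir: str | Path, header: str | None = None) -> None:
        """spikes.csv, memory.csv, lesions.csv and summary.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

        def _write(df: pd.DataFrame, name: str) -> None:
            path = out / name
            with open(path, "w") as fh:
                if header:
                    fh.write(f"# {header}\n")
                df.to_csv(fh, index=False)

        _write(self.to_spikes_frame(), "spikes.csv")
        _write(self.to_memory_frame(), "memory.csv")
        lesions = self.config_echo.get("lesion_events", [])
        _write(
            pd.DataFrame(lesions, columns=["t_ms", "connection_id"]), "lesions.csv"
        )
        summary = {
            cid: {
                "spike_count": self.spike_count(cid),
                "mean_rate_hz": self.spike_count(cid) / (self.duration / 1000.0),
            }
            for cid in self.cell_ids
        }
        (out / "summary.json").write_text(
            json.dumps({"seed": self.seed, "cells": summary}, indent=2)
        )


def step_count(duration: float, dt: float) -> int:
    """Number of 0.5 ms cycles for a run (duration / dt)."""
    n = duration / dt
    if abs(n - round(n)) > 1e-9:
        raise ConfigurationError("duration must be an integer multiple of dt")
    return int(round(n))


def _build_input_trains(
    network: NetworkConfig, duration: float, seed: int | None
) -> dict[str, InputSpikeTrains]:
    s = network.input_settings
    rates = {**DEFAULT_INPUT_RATES, **{k: v for k, v in s.items() if k in DEFAULT_INPUT_RATES}}
    ss = np.random.SeedSequence(seed)
    child = {pid: np.random.default_rng(c) for pid, c in
             zip(("EC2", "EC3", "DG", "MS"), ss.spawn(4))}
    pops = {
        "EC2": InputPopulation("EC2", s.get("n_ec_cells", 100), rates["ec_rate_peak"],
                               rates["theta_freq"], rates["ec2_phase"]),
        "EC3": InputPopulation("EC3", s.get("n_ec_cells", 100), rates["ec_rate_peak"],
                               rates["theta_freq"], rates["ec3_phase"]),
        "DG": InputPopulation("DG", s.get("n_dg_cells", 100), rates["dg_rate_peak"],
                              rates["theta_freq"], rates["dg_phase"]),
        "MS": InputPopulation("MS", 6, rates["ms_rate_peak"],
                              rates["theta_freq"], rates["ms_phase"]),
    }
    return {
        pid: generate_theta_population(pop, duration, rng=child[pid])
        for pid, pop in pops.items()
    }


def run(
    network: NetworkConfig,
    duration: float = 10000.0,
    seed: int | None = 0,
    lesion_schedule: LesionSchedule | None = None,
    record_every: int = 10,
    input_trains: dict[str, InputSpikeTrains] | None = None,
    record_drive: bool = False,
) -> SimulationResult:
    """Simulate the network for ``duration`` ms at 0.5 ms resolution.

    ``lesion_schedule`` (possibly empty) turns the run into the pathology
    condition; with an empty schedule the output is bit-identical to a
    control run at the same seed. ``input_trains`` may replay previously
    generated or recorded inputs; by default fresh theta-modulated trains
    are drawn from ``seed``.

    The memory trace records, every ``record_every`` cycles, the mean LTP
    multiplier over each pyramidal cell's excitatory compartments,
    together with the cumulative deleted-synapse count on the same time
    base.
    """
    network = copy.deepcopy(network)  # runs never mutate the caller's wiring
    const = network.constants
    dt, ReP = const.dt, const.ReP
    n_cycles = step_count(duration, dt)
    cells = list(network.cells)
    cell_index = {cid: i for i, cid in enumerate(cells)}
    n_cells = len(cells)
    n_comp = N_COMPARTMENTS_PER_CELL

    # --- PSP templates per (target cell, receptor) ------------------------
    tpl_cache: dict[tuple[float, str], np.ndarray] = {}

    def template_for(peak: float, receptor: str) -> np.ndarray:
        key = (peak, receptor)
        if key not in tpl_cache:
            rise, decay = PSP_TAUS[receptor]
            kind = "inhibitory" if peak < 0 else "excitatory"
            tpl_cache[key] = build_template(kind, peak, rise, decay, dt=dt).values
        return tpl_cache[key]

    conns = network.connections
    conn_targets = np.array([cell_index[c.target] for c in conns])
    conn_comp = np.array([c.target_compartment for c in conns])
    conn_delay = np.array([c.delay_boxes for c in conns])
    deleted = np.array([c.deleted for c in conns])
    conn_templates: list[list[tuple[int, np.ndarray]]] = []  # (register id, tpl)
    REG_E, REG_M, REG_I = 0, 1, 2
    for c in conns:
        epsp = network.cells[c.target].params.EPSPd
        ipsp = network.cells[c.target].params.IPSPd
        tl: list[tuple[int, np.ndarray]] = []
        for rec in c.receptors:
            if rec == "AMPA":
                tl.append((REG_E, template_for(epsp, "AMPA")))
            elif rec == "NMDA":
                tl.append((REG_M, template_for(epsp, "NMDA")))
            else:
                tl.append((REG_I, template_for(ipsp, "GABA_A")))
        conn_templates.append(tl)
    conn_excit = np.array([c.is_excitatory for c in conns])

    max_support = max(t.size for tl in conn_templates for _, t in tl)
    L = 2 * max_support
    if L < max_support + int(conn_delay.max(initial=0)):
        raise ConfigurationError("register length shorter than template + delay")

    # --- compartment weights, thresholds, plasticity masks ----------------
    w_base = np.zeros((n_cells, n_comp))
    for cid, spec in network.cells.items():
        i = cell_index[cid]
        w_base[i, 1] = 1.0  # soma
    for c in conns:
        w_base[cell_index[c.target], c.target_compartment] = max(
            w_base[cell_index[c.target], c.target_compartment], c.base_weight
        )
    thresholds = np.array([network.cells[c].params.spike_threshold for c in cells])
    fq = np.array([network.cells[c].params.FQ for c in cells])[:, None]
    exc_mask = np.zeros((n_cells, n_comp), dtype=bool)
    for c in conns:
        if c.is_excitatory:
            exc_mask[cell_index[c.target], c.target_compartment] = True
    pcs = [cid for cid in cells if network.cells[cid].params.cell_type == "pyramidal"]

    pl = network.plasticity
    CaMT, decay_every = pl.CaMT, pl.decay_every

    # --- input spike trains -> per-cycle delivery queue -------------------
    if input_trains is None:
        input_trains = _build_input_trains(network, duration, seed)
    due: dict[int, list[int]] = defaultdict(list)
    for j, c in enumerate(conns):
        if c.source in input_trains:
            trains = input_trains[c.source].trains
            for sc in c.source_cells:
                for t in trains[sc]:
                    cyc = int(t // dt) + c.delay_boxes
                    if cyc < n_cycles:
                        due[cyc].append(j)
    outgoing: dict[int, list[int]] = defaultdict(list)  # source cell -> conns
    for j, c in enumerate(conns):
        if c.source in cell_index:
            outgoing[cell_index[c.source]].append(j)

    # --- lesion events -> cycles ------------------------------------------
    schedule = lesion_schedule or LesionSchedule([])
    lesion_events = sorted(schedule.events, key=lambda e: e.time_ms)
    conn_id_index = {c.id: j for j, c in enumerate(conns)}
    lesion_ptr = 0
    lesion_log: list[tuple[float, str]] = []

    # --- state -------------------------------------------------------------
    E = np.full((n_cells, n_comp, L), ReP)
    M = np.full((n_cells, n_comp, L), ReP)
    I = np.full((n_cells, n_comp, L), ReP)
    regs = (E, M, I)
    head = 0
    refrac = np.zeros(n_cells, dtype=int)
    C = np.zeros((n_cells, n_comp))
    m_mult = np.ones((n_cells, n_comp))
    spikes: list[list[float]] = [[] for _ in range(n_cells)]

    n_rec = n_cycles // record_every + 1
    trace_t = np.empty(n_rec)
    traces = {cid: np.empty(n_rec) for cid in pcs}
    del_series = np.empty(n_rec, dtype=int)
    rec_i = 0
    offsets = np.arange(L)
    drive_log = np.empty((n_cells, n_cycles)) if record_drive else None

    for cyc in range(n_cycles):
        t_ms = cyc * dt

        # (1) due lesions
        while lesion_ptr < len(lesion_events) and lesion_events[lesion_ptr].time_ms <= t_ms:
            ev = lesion_events[lesion_ptr]
            deleted[conn_id_index[ev.connection_id]] = True
            lesion_log.append((ev.time_ms, ev.connection_id))
            lesion_ptr += 1

        # (2) deliver spikes scheduled for this cycle
        arrivals = np.zeros((n_cells, n_comp), dtype=bool)
        events = due.pop(cyc, None)
        if events:
            for j in events:
                if deleted[j]:
                    continue
                tgt = conn_targets[j]
                if refrac[tgt] > 0:  # compartments inhibited while refractory
                    continue
                k = conn_comp[j]
                for reg_id, tpl in conn_templates[j]:
                    idx = offsets[: tpl.size] + head
                    idx[idx >= L] -= L
                    regs[reg_id][tgt, k, idx] += tpl
                if conn_excit[j]:
                    arrivals[tgt, k] = True

        # (3) local potentials and weighted somatic drives
        S = E[:, :, head] + M[:, :, head] + I[:, :, head] - 2.0 * ReP
        drive = ReP + ((w_base * m_mult) * (S - ReP)).sum(axis=1)
        if drive_log is not None:
            drive_log[:, cyc] = drive

        # (4) memory rule: NMDA-gated charge accumulation
        gated = arrivals & exc_mask & (S > CaMT)
        if gated.any():
            dv = (M[:, :, head][gated] - ReP) / 1000.0  # mV -> V
            C[gated] += np.expm1(10.0 * dv)
        if (cyc + 1) % decay_every == 0:  # slow forgetting step
            C = np.where(C > fq, C - fq, C)
            np.clip(C, 0.0, None, out=C)
        m_mult = memory_multiplier_array(C)

        # (5) threshold, spike, reset, refractoriness
        firing = (drive > thresholds) & (refrac == 0)
        refrac[refrac > 0] -= 1
        if firing.any():
            for i in np.nonzero(firing)[0]:
                spikes[i].append(t_ms)
                E[i] = ReP
                M[i] = ReP
                I[i] = ReP
                refrac[i] = const.refractory_cycles
                for j in outgoing.get(i, ()):
                    due[cyc + conn_delay[j]].append(j)

        # (6) advance all registers: head box becomes the fresh tail
        E[:, :, head] = ReP
        M[:, :, head] = ReP
        I[:, :, head] = ReP
        head += 1
        if head == L:
            head = 0

        if cyc % record_every == 0:
            trace_t[rec_i] = t_ms
            for cid in pcs:
                i = cell_index[cid]
                traces[cid][rec_i] = m_mult[i][exc_mask[i]].mean()
            del_series[rec_i] = int(deleted.sum())
            rec_i += 1

    return SimulationResult(
        spike_trains={cid: np.array(spikes[cell_index[cid]]) for cid in cells},
        trace_time_ms=trace_t[:rec_i],
        memory_traces={cid: tr[:rec_i] for cid, tr in traces.items()},
        deletion_series=del_series[:rec_i],
        duration=duration,
        seed=seed,
        dt=dt,
        config_echo={
            "n_cells": n_cells,
            "n_connections": len(conns),
            "lesion_events": lesion_log,
            "input_settings": dict(network.input_settings),
        },
        input_trains=input_trains,
        drive_traces=(
            {cid: drive_log[cell_index[cid]] for cid in cells}
            if drive_log is not None
            else None
        ),
    )
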