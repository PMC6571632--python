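"""Theta-modulated stochastic input spike trains.

The microcircuit is driven by four external sources: entorhinal cortex
layer 2 (EC2, to CA3), entorhinal cortex layer 3 (EC3, to CA1, in
antiphase with EC2), dentate-gyrus mossy-fiber drive (DG, relayed onto CA3
pyramidal cells) and the GABAergic theta pacemaker of the medial
septum-diagonal band (MS, six cells T1-T6 onto basket and O-LM somas).
Each source cell fires as an inhomogeneous Poisson process whose rate is a
half-wave-rectified 8 Hz cosine, r(t) = rate_peak * max(0, cos(2*pi*f*t +
phase)), so EC2 and EC3 (phases 0 and pi) are strong on opposite theta
half-cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "InputPopulation",
    "InputSpikeTrains",
    "generate_theta_population",
    "generate_ms_theta",
    "population_rate",
    "spectral_peak_hz",
]

THETA_HZ = 8.0


@dataclass(frozen=True)
class InputPopulation:
    """Description of one stochastic input source."""

    id: str  # EC2 | EC3 | DG | MS
    n_cells: int = 100
    rate_peak: float = 20.0  # Hz, per cell at the theta maximum
    theta_freq: float = THETA_HZ
    phase: float = 0.0  # radians
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.theta_freq <= 0:
            raise ValueError("theta frequency must be positive")
        if self.rate_peak < 0:
            raise ValueError("rate_peak must be >= 0")
        if self.n_cells < 1:
            raise ValueError("population needs at least one cell")


@dataclass
class InputSpikeTrains:
    """Per-source-cell spike times in ms, sorted, within [0, duration]."""

    population: InputPopulation
    duration: float
    trains: list[np.ndarray] = field(default_factory=list)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))

    def all_times(self) -> np.ndarray:
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate(self.trains))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (f"{self.population.id}_{i}", t)
            for i, train in enumerate(self.trains)
            for t in train
        ]
        return pd.DataFrame(rows, columns=["cell_id", "spike_time_ms"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rate_fraction(t_ms: np.ndarray, freq: float, phase: float) -> np.ndarray:
    """r(t)/rate_peak: half-wave rectified theta cosine."""
    return np.maximum(0.0, np.cos(2.0 * np.pi * freq * t_ms / 1000.0 + phase))


def generate_theta_population(
    pop: InputPopulation,
    duration: float,
    rng: np.random.Generator | None = None,
) -> InputSpikeTrains:
    """Sample every source cell of a theta-modulated population.

    Inhomogeneous Poisson sampling by thinning: candidate spikes are drawn
    at the constant peak rate and kept with probability r(t)/rate_peak.
    Identical (population, duration, seed) always yield identical trains.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if rng is None:
        rng = np.random.default_rng(pop.seed)
    trains: list[np.ndarray] = []
    for _ in range(pop.n_cells):
        if duration == 0 or pop.rate_peak == 0:
            trains.append(np.empty(0))
            continue
        n_cand = rng.poisson(pop.rate_peak * duration / 1000.0)
        cand = np.sort(rng.uniform(0.0, duration, n_cand))
        keep = rng.uniform(size=n_cand) < _rate_fraction(
            cand, pop.theta_freq, pop.phase
        )
        trains.append(cand[keep])
    return InputSpikeTrains(pop, duration, trains)


def generate_ms_theta(
    duration: float,
    phase: float = np.pi,
    seed: int | None = None,
    n_cells: int = 6,
    rate_peak: float = 60.0,
    theta_freq: float = THETA_HZ,
) -> InputSpikeTrains:
    """Medial-septum GABAergic pacemaker trains (T1-T6).

    Theta-rhythmic at 8 Hz, by default in antiphase with EC2 so somatic
    inhibition of interneurons is strongest when EC2 drive is weak.
    """
    pop = InputPopulation(
        id="MS",
        n_cells=n_cells,
        rate_peak=rate_peak,
        theta_freq=theta_freq,
        phase=phase,
        seed=seed,
    )
    return generate_theta_population(pop, duration)


def population_rate(
    trains: InputSpikeTrains, bin_ms: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Binned population spike count: (bin centers in ms, counts)."""
    edges = np.arange(0.0, trains.duration + bin_ms, bin_ms)
    counts, _ = np.histogram(trains.all_times(), bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts.astype(float)


def spectral_peak_hz(trains: InputSpikeTrains, bin_ms: float = 5.0) -> float:
    """Frequency of the largest non-DC peak of the population-count power
    spectrum (Hz) — the dominant modulation frequency of the source."""
    from scipy import signal

    _, counts = population_rate(trains, bin_ms)
    fs = 1000.0 / bin_ms
    freqs, power = signal.periodogram(counts - counts.mean(), fs=fs)
    if power[1:].sum() == 0:
        raise ValueError("population train has no spectral content")
    return float(freqs[1:][np.argmax(power[1:])])
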