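"""Spike-train statistics and healthy-vs-pathology comparisons.

Per-cell summaries (counts, interspike intervals, mean and final firing
frequency, mean memory), correlations of activity or memory against the
cumulative synaptic-deletion series, and two-group tests (Student t or
Mann-Whitney U, auto-selected by a Shapiro-Wilk normality pre-check).

Two frequency notions are exposed: the instantaneous mean frequency is
the mean of 1/ISI over a cell's interspike intervals (the default, whose
SD can exceed the mean for bursty trains), while the count rate is
spike_count / duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SimulationResult

__all__ = [
    "CellSummary",
    "summarize",
    "summary_frame",
    "deletion_correlation",
    "compare_groups",
    "memory_vs_deletion",
]


@dataclass
class CellSummary:
    cell_id: str
    spike_count: int
    mean_frequency: float  # Hz, mean of instantaneous 1/ISI frequencies
    count_rate: float  # Hz, spike_count / duration
    final_frequency: float  # Hz, over the terminal window
    isi_ms: np.ndarray = field(repr=False)
    mean_memory: float = 1.0


def _summary_for(
    cell_id: str,
    train: np.ndarray,
    duration: float,
    final_window: float,
    mean_memory: float,
) -> CellSummary:
    train = np.sort(np.asarray(train, dtype=float))
    isi = np.diff(train)
    inst = float(np.mean(1000.0 / isi)) if isi.size else 0.0
    n_final = int(np.count_nonzero(train >= duration - final_window))
    return CellSummary(
        cell_id=cell_id,
        spike_count=int(train.size),
        mean_frequency=inst,
        count_rate=train.size / (duration / 1000.0),
        final_frequency=n_final / (final_window / 1000.0),
        isi_ms=isi,
        mean_memory=mean_memory,
    )


def summarize(
    result: SimulationResult, final_window: float = 1000.0
) -> list[CellSummary]:
    """Per-cell activity summary of one run.

    ``final_window`` (ms, default the last second) defines the terminal
    window for the final firing frequency.
    """
    if final_window > result.duration:
        raise ValueError("final_window exceeds the run duration")
    out = []
    for cid, train in result.spike_trains.items():
        mem = (
            float(result.memory_traces[cid].mean())
            if cid in result.memory_traces
            else 1.0
        )
        out.append(_summary_for(cid, train, result.duration, final_window, mem))
    return out


def summary_frame(summaries: list[CellSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in summaries],
            "spike_count": [s.spike_count for s in summaries],
            "mean_frequency_hz": [s.mean_frequency for s in summaries],
            "count_rate_hz": [s.count_rate for s in summaries],
            "final_frequency_hz": [s.final_frequency for s in summaries],
            "mean_memory": [s.mean_memory for s in summaries],
        }
    )


def deletion_correlation(
    metric_series: np.ndarray,
    deletion_series: np.ndarray,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlate an activity/memory series against cumulative deletions.

    Returns (r, two-sided p). Series must be aligned and of equal length;
    a zero-variance series has no defined correlation and raises.
    """
    x = np.asarray(metric_series, dtype=float)
    y = np.asarray(deletion_series, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must be aligned and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 aligned samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: a series has zero variance")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r.statistic), float(r.pvalue)


def compare_groups(
    a, b, test: str | None = None, alpha_normality: float = 0.05
) -> tuple[float, float, str]:
    """Two-sided two-group comparison.

    ``test`` is "t", "mannwhitney", or None to auto-select: Student t if
    both groups pass a Shapiro-Wilk normality pre-check at
    ``alpha_normality``, Mann-Whitney U otherwise. Returns
    (statistic, p, test_used). Degenerate identical-constant samples give
    p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.std(a) == 0 and np.std(b) == 0 and a.size and b.size and a[0] == b[0]:
        warnings.warn("degenerate identical samples; p = 1", RuntimeWarning)
        return 0.0, 1.0, test or "degenerate"
    if test is None:
        normal = True
        for g in (a, b):
            if g.size >= 3 and np.std(g) > 0:
                normal &= stats.shapiro(g).pvalue > alpha_normality
            else:
                normal = False
        test = "t" if normal else "mannwhitney"
    if test == "t":
        if min(a.size, b.size) < 2:
            raise ValueError("t test needs n >= 2 per group")
        res = stats.ttest_ind(a, b)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError("test must be 't' or 'mannwhitney'")
    return float(res.statistic), float(res.pvalue), test


def memory_vs_deletion(
    result_control: SimulationResult,
    result_pathology: SimulationResult,
    cells: tuple[str, ...] = ("P1", "P5"),
) -> dict[str, pd.DataFrame]:
    """Aligned (deletion, memory) and (spike count, memory) series.

    For each requested pyramidal cell, pairs the cumulative-deletion
    series of each run with that cell's memory trace on the shared time
    base, plus the cumulative spike count over the same trace times, for
    both the control and the pathology run.
    """
    if result_control.trace_time_ms.shape != result_pathology.trace_time_ms.shape:
        raise ValueError("runs do not share a time base")
    out: dict[str, pd.DataFrame] = {}
    for cid in cells:
        frames = {}
        for label, res in (("control", result_control), ("pathology", result_pathology)):
            t = res.trace_time_ms
            cum_spikes = np.searchsorted(np.sort(res.spike_trains[cid]), t, side="right")
            frames[label] = pd.DataFrame(
                {
                    "t_ms": t,
                    "cumulative_deletion": res.deletion_series,
                    "mean_memory": res.memory_traces[cid],
                    "cumulative_spikes": cum_spikes,
                }
            )
        out[cid] = pd.concat(frames, names=["condition"]).reset_index(level=0).rename(
            columns={"level_0": "condition"}
        )
    return out
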