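"""Chaos-theoretic characterization of simulated spike-train series.

Given a one-dimensional series (by default a cell's interspike-interval
sequence), the suite reconstructs the attractor by time-delay embedding,
chooses the delay from the autocorrelation function (first drop below
1/e), selects the minimal embedding dimension with the false-nearest-
neighbors criterion, estimates the Grassberger-Procaccia correlation
dimension D2, computes the Shannon entropy of the amplitude histogram,
and builds the matrix of all pairwise Euclidean distances between
embedded 3-D points (the recurrence-plot distance matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "EmbeddingParams",
    "NLAResult",
    "embed",
    "delay_from_autocorrelation",
    "fnn_fractions",
    "fnn_embedding_dimension",
    "correlation_dimension",
    "shannon_entropy",
    "recurrence_matrix",
    "nla_summary",
]


@dataclass(frozen=True)
class EmbeddingParams:
    delay: int  # tau, in samples
    dimension: int  # m

    def __post_init__(self) -> None:
        if self.delay < 1 or self.dimension < 1:
            raise ValueError("embedding requires tau >= 1 and m >= 1")


@dataclass
class NLAResult:
    embedding_dimension: int
    correlation_dimension: float
    entropy_bits: float
    delay: int
    recurrence: np.ndarray = field(repr=False, default=None)


def embed(series: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay-embed a series into (n_points, m) phase-space vectors."""
    x = np.asarray(series, dtype=float)
    n = x.size - (m - 1) * tau
    if n < 1:
        raise ValueError(
            f"series too short for m={m}, tau={tau}: need > {(m - 1) * tau} samples"
        )
    return np.column_stack([x[i * tau : i * tau + n] for i in range(m)])


def delay_from_autocorrelation(series: np.ndarray) -> int:
    """Embedding delay: first lag where the autocorrelation falls to 1/e.

    Falls back to the first local minimum of the autocorrelation if it
    never drops below 1/e; constant series have no defined delay.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0:
        raise ValueError("autocorrelation undefined for a constant series")
    acf = np.correlate(x, x, mode="full")[x.size - 1 :] / var
    below = np.nonzero(acf <= 1.0 / np.e)[0]
    if below.size:
        return max(int(below[0]), 1)
    minima = np.nonzero((acf[1:-1] < acf[:-2]) & (acf[1:-1] < acf[2:]))[0]
    return int(minima[0]) + 1 if minima.size else 1


def fnn_fractions(
    series: np.ndarray,
    tau: int,
    m_max: int,
    Rtol: float = 15.0,
    Atol: float = 2.0,
) -> np.ndarray:
    """False-nearest-neighbor fraction for m = 1..m_max (Kennel criteria).

    A neighbor is false when adding the (m+1)-th coordinate stretches the
    neighbor distance by more than ``Rtol``, or when the stretched
    distance exceeds ``Atol`` attractor radii (the amplitude criterion
    that keeps noise flagged at every dimension). Temporal neighbors
    within one delay are excluded (Theiler window).
    """
    x = np.asarray(series, dtype=float)
    sigma = x.std()
    fracs = np.empty(m_max)
    for m in range(1, m_max + 1):
        pts = embed(x, m, tau)
        pts_next = embed(x, m + 1, tau)
        n = pts_next.shape[0]
        if n < 10:
            raise ValueError(
                f"series too short for FNN at m={m + 1}: need > {m * tau + 10} samples"
            )
        d = squareform(pdist(pts[:n]))
        idx = np.arange(n)
        theiler = np.abs(idx[:, None] - idx[None, :]) <= tau
        d[theiler] = np.inf
        nn = d.argmin(axis=1)
        dist_m = d[idx, nn]
        extra = np.abs(pts_next[idx, m] - pts_next[nn, m])
        dist_next = np.hypot(dist_m, extra)
        with np.errstate(invalid="ignore", divide="ignore"):
            false = (extra / dist_m > Rtol) | (dist_next / sigma > Atol)
        valid = np.isfinite(dist_m) & (dist_m > 0)
        fracs[m - 1] = false[valid].mean() if valid.any() else 1.0
    return fracs


def fnn_embedding_dimension(
    series: np.ndarray,
    tau: int,
    m_max: int = 8,
    Rtol: float = 15.0,
    frac_tol: float = 0.01,
) -> int:
    """Smallest embedding dimension with < 1% false nearest neighbors.

    If no dimension up to ``m_max`` reaches the tolerance (e.g. white
    noise, which has no finite embedding), returns ``m_max`` with a
    warning.
    """
    fracs = fnn_fractions(series, tau, m_max, Rtol)
    ok = np.nonzero(fracs < frac_tol)[0]
    if ok.size:
        return int(ok[0]) + 1
    warnings.warn(
        "no embedding dimension reached the false-neighbor tolerance; "
        "series may be noise-dominated",
        RuntimeWarning,
    )
    return m_max


def correlation_dimension(
    series: np.ndarray,
    m: int,
    tau: int,
    r_grid: np.ndarray | None = None,
    theiler: int | None = None,
) -> float:
    """Grassberger-Procaccia correlation dimension D2.

    The correlation sum C(r) counts pairs of embedded points closer than
    r, excluding temporally close pairs (Theiler window, default = tau);
    D2 is the slope of log C(r) vs log r fitted over the scaling region
    (middle two quartiles of the r grid).
    """
    pts = embed(series, m, tau)
    n = pts.shape[0]
    if n < 100:
        raise ValueError("need at least 100 embedded points")
    theiler = tau if theiler is None else theiler
    d = pdist(pts)
    ii, jj = np.triu_indices(n, k=1)
    d = d[(jj - ii) > theiler]
    d = d[d > 0]
    if d.size == 0:
        return 0.0  # a single repeated point: zero-dimensional
    if r_grid is None:
        # small-radius scaling region, away from attractor-size saturation
        lo, hi = np.quantile(d, [0.001, 0.1])
        lo = max(lo, hi * 1e-4)
        if lo <= 0 or lo >= hi:
            raise ValueError("degenerate scaling region: distances collapse")
        r_grid = np.geomspace(lo, hi, 24)
    counts = np.searchsorted(np.sort(d), r_grid, side="right")
    q = len(r_grid) // 4
    sel = slice(q, len(r_grid) - q)  # middle quartiles = scaling region
    r_sel, c_sel = r_grid[sel], counts[sel]
    mask = c_sel > 0
    if mask.sum() < 2:
        raise ValueError("degenerate scaling region: too few populated radii")
    slope = np.polyfit(np.log(r_sel[mask]), np.log(c_sel[mask]), 1)[0]
    return float(slope)


def shannon_entropy(series: np.ndarray, n_bins: int = 16) -> float:
    """Shannon entropy (bits) of the series' amplitude histogram.

    H = -sum p log2 p over an ``n_bins`` histogram spanning the sample
    range; 0 for a constant series, log2(n_bins) for a uniform one.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def recurrence_matrix(series: np.ndarray, tau: int, m: int = 3) -> np.ndarray:
    """All pairwise Euclidean distances between delay-embedded points.

    The 3-D phase-space distance matrix underlying a recurrence plot:
    symmetric, non-negative, zero on the diagonal.
    """
    pts = embed(series, m, tau)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 embedded points")
    return squareform(pdist(pts))


def nla_summary(
    series: np.ndarray,
    m_max: int = 8,
    n_bins: int = 16,
    with_recurrence: bool = False,
) -> NLAResult:
    """Run the full nonlinear suite on one series."""
    tau = delay_from_autocorrelation(series)
    m = fnn_embedding_dimension(series, tau, m_max=m_max)
    try:
        d2 = correlation_dimension(series, max(m, 2), tau)
    except ValueError:
        d2 = float("nan")
    return NLAResult(
        embedding_dimension=m,
        correlation_dimension=d2,
        entropy_bits=shannon_entropy(series, n_bins),
        delay=tau,
        recurrence=recurrence_matrix(series, tau) if with_recurrence else None,
    )
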