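"""Delay embedding, recurrence plots and the τ-recurrence rate.

A recurrence plot (RP) marks the pairs of times at which a trajectory
returns to within a threshold ε of a previously visited state:
``R(i,j) = Θ(ε − ‖x(i) − x(j)‖)``.  Rather than fixing ε directly, the
threshold is chosen as an empirical quantile of the pairwise-distance
multiset so that the RP attains a prescribed recurrence-point density,
making RPs of different systems comparable.

The τ-recurrence rate ``RR(τ)`` is the mean of the τ-th superdiagonal of R
— an estimate of the probability that the system returns to a former state
after a lag of τ samples.  Peaks of RR(τ) sit at the oscillation period and
its multiples, which is what the phase-synchronization measures in
:mod:`neurorqa.sync` compare between two systems.

Scalar series are reconstructed by (possibly multi-delay) time-delay
embedding; the delays used for the bursting regimes studied here are
shipped as :data:`EMBEDDING_PRESETS`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "EmbeddingSpec",
    "RecurrencePlot",
    "TauRecurrenceSeries",
    "EMBEDDING_PRESETS",
    "delay_embed",
    "threshold_for_density",
    "recurrence_matrix",
    "tau_recurrence_rate",
    "tau_recurrence_rate_streaming",
    "decimate_series",
    "rr_tau_pipeline",
]

_NORMS = {"euclidean": "euclidean", "supremum": "chebyshev", "taxicab": "cityblock"}


@dataclass(frozen=True)
class EmbeddingSpec:
    """Time-delay embedding: dimension m and m−1 positive integer lags.

    ``delays=(17, 22)`` with ``dimension=3`` maps ``x`` to vectors
    ``(x(i), x(i+17), x(i+22))`` — the multi-delay convention produced by
    automated embedding-selection algorithms.
    """

    dimension: int
    delays: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("embedding dimension must be >= 1")
        if len(self.delays) != self.dimension - 1:
            raise ValueError("need exactly dimension-1 delays")
        d = np.asarray(self.delays, dtype=int)
        if d.size and (np.any(d <= 0) or np.any(np.diff(d) <= 0)):
            raise ValueError("delays must be positive and strictly increasing")

    @property
    def max_delay(self) -> int:
        return max(self.delays) if self.delays else 0


#: Embedding parameters for the four bursting regimes of the forced neuron
#: (selected with the PECUZAL continuity statistic; shipped as fixed presets).
EMBEDDING_PRESETS: dict[str, EmbeddingSpec] = {
    "4_spike": EmbeddingSpec(3, (17, 22)),
    "2_spike": EmbeddingSpec(2, (16,)),
    "chaos": EmbeddingSpec(2, (20,)),
    "1_spike": EmbeddingSpec(2, (19,)),
}


@dataclass
class RecurrencePlot:
    """Binary N×N recurrence matrix with the threshold and embedding used."""

    R: np.ndarray
    epsilon: float
    target_density: float | None = None
    embedding: EmbeddingSpec | None = None
    norm: str = "euclidean"

    @property
    def n(self) -> int:
        return self.R.shape[0]

    @property
    def density(self) -> float:
        return float(self.R.mean())


@dataclass
class TauRecurrenceSeries:
    """RR(τ) series on an integer lag grid; ``dt`` converts lags to ms."""

    tau: np.ndarray
    rr: np.ndarray
    dt: float = 1.0

    @property
    def tau_ms(self) -> np.ndarray:
        return self.tau * self.dt

    def __len__(self) -> int:
        return len(self.tau)


def delay_embed(series: np.ndarray, spec: EmbeddingSpec) -> np.ndarray:
    """Embed a scalar series into spec.dimension-dimensional state vectors.

    Returns an ``(N − max_delay, m)`` array whose k-th row is
    ``(x(k), x(k+d1), …)``; dimension 1 is the identity embedding.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size <= spec.max_delay:
        raise ValueError("series shorter than the largest embedding delay")
    n = x.size - spec.max_delay
    cols = [x[:n]] + [x[d : d + n] for d in spec.delays]
    return np.column_stack(cols)


def threshold_for_density(
    vectors: np.ndarray, target_density: float, norm: str = "euclidean"
) -> float:
    """Threshold ε whose RP attains the requested recurrence-point density.

    ε is the ``round(target·N²)``-th smallest element of the full N²
    pairwise-distance multiset (the N diagonal zeros included), so that with
    the inclusive recurrence rule ``d ≤ ε`` the achieved density matches the
    target up to ties.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two state vectors")
    if not 0.0 < target_density <= 1.0:
        raise ValueError("target density must be in (0, 1]")
    d = pdist(X, metric=_NORMS[norm])
    k = int(round(target_density * n * n))
    if k <= n:
        return 0.0
    j = int(np.ceil((k - n) / 2.0))  # each off-diagonal distance occurs twice
    j = min(j, d.size)
    return float(np.partition(d, j - 1)[j - 1])


def recurrence_matrix(
    vectors: np.ndarray,
    epsilon: float,
    norm: str = "euclidean",
    target_density: float | None = None,
    embedding: EmbeddingSpec | None = None,
) -> RecurrencePlot:
    """Binary recurrence matrix R(i,j) = 1 iff ‖x(i) − x(j)‖ ≤ ε.

    Distances exactly equal to ε count as recurrent (Heaviside Θ(0)=1), so a
    quantile-derived ε hits its target density on ties.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("state vectors must be finite")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    D = squareform(pdist(X, metric=_NORMS[norm]))
    R = D <= epsilon
    return RecurrencePlot(R, float(epsilon), target_density, embedding, norm)


def tau_recurrence_rate(rp: RecurrencePlot, dt: float = 1.0) -> TauRecurrenceSeries:
    """RR(τ) = mean of the τ-th superdiagonal of a materialized RP."""
    n = rp.n
    rr = np.empty(n)
    for tau in range(n):
        rr[tau] = np.diagonal(rp.R, offset=tau).mean()
    return TauRecurrenceSeries(np.arange(n), rr, dt)


def tau_recurrence_rate_streaming(
    vectors: np.ndarray,
    epsilon: float,
    norm: str = "euclidean",
    dt: float = 1.0,
) -> TauRecurrenceSeries:
    """RR(τ) computed diagonal-by-diagonal without materializing the RP.

    Exactly equal to :func:`tau_recurrence_rate` of the corresponding RP,
    but with O(N) memory; this is the form used by the scan pipelines.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("state vectors must be finite")
    n = X.shape[0]
    rr = np.empty(n)
    rr[0] = 1.0
    if norm == "euclidean":
        eps2 = epsilon * epsilon
        for tau in range(1, n):
            diff = X[tau:] - X[:-tau]
            rr[tau] = np.mean(np.einsum("ij,ij->i", diff, diff) <= eps2)
    else:
        for tau in range(1, n):
            d = cdist(X[tau:], X[:-tau], metric=_NORMS[norm])
            rr[tau] = np.mean(np.diagonal(d) <= epsilon)
    return TauRecurrenceSeries(np.arange(n), rr, dt)


def decimate_series(
    x: np.ndarray, dt: float, max_samples: int = 5000
) -> tuple[np.ndarray, float, int]:
    """Point-decimate a series to at most ``max_samples`` samples.

    Returns (decimated series, effective dt, decimation factor).  Simple
    point sampling is used (no low-pass filter): recurrence structure lives
    in the slow bursting geometry, and RR(τ) peak positions in ms are
    insensitive to the decimation factor.
    """
    x = np.asarray(x, dtype=float)
    factor = max(1, int(np.ceil(x.shape[0] / max_samples)))
    return x[::factor], dt * factor, factor


def rr_tau_pipeline(
    series: np.ndarray,
    dt: float,
    *,
    embedding: EmbeddingSpec,
    density: float = 0.1,
    norm: str = "euclidean",
    max_samples: int = 5000,
) -> TauRecurrenceSeries:
    """Scalar series → decimation → embedding → fixed-density ε → RR(τ)."""
    x, dt_eff, _ = decimate_series(series, dt, max_samples)
    X = delay_embed(x, embedding)
    eps = threshold_for_density(X, density, norm)
    return tau_recurrence_rate_streaming(X, eps, norm, dt_eff)
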