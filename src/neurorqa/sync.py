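"""Recurrence-based phase-synchronization measures and surrogate testing.

Two oscillators are compared through their τ-recurrence-rate series RR(τ)
(see :mod:`neurorqa.recurrence`): when the systems are phase synchronized
their probabilities of recurrence peak at the same lags, so the two RR(τ)
series are similar.  Three scalar measures quantify this:

* ``cpr_pearson`` — the classical correlation of probability of recurrence
  (Pearson correlation of the two RR(τ) series); 1 ≈ phase synchronization.
* ``cpr_spearman`` — the same on rank-transformed series, less sensitive to
  the spiky, non-normal shape of RR(τ).
* ``hellinger`` — RR(τ) estimates a probability of recurrence, so the two
  series (normalized to unit sum) can be compared as probability
  distributions with the Hellinger metric H = (1/√2)·‖√p − √q‖₂ ∈ [0, 1];
  values near 0 indicate phase synchronization.

Lags below a Theiler window (default 25 ms) are excluded: the RR(τ) peak at
τ≈0 comes from the main diagonal of every RP and would fake similarity
between unrelated systems.

Significance of a small H is assessed against block-shuffle surrogates:
one voltage series is cut into equal-width blocks whose order is randomly
permuted, destroying long-range phase relations while keeping short-term
structure; the 95% quantile of the surrogate H distribution is the
confidence limit below which H indicates genuine phase synchronization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import CoupledConfig, simulate_coupled
from .recurrence import EmbeddingSpec, TauRecurrenceSeries, rr_tau_pipeline
from .spikes import frequency_mismatch

__all__ = [
    "SyncResult",
    "RecurrencePipelineConfig",
    "apply_theiler",
    "cpr_pearson",
    "cpr_spearman",
    "hellinger",
    "sync_measures",
    "block_shuffle",
    "surrogate_confidence_limit",
    "synchronization_scan",
    "sync_onset",
]


@dataclass(frozen=True)
class RecurrencePipelineConfig:
    """Fixed recurrence pipeline for synchronization analysis: decimation cap,
    embedding, recurrence-point density, norm and Theiler window (ms)."""

    embedding: EmbeddingSpec = field(default_factory=lambda: EmbeddingSpec(2, (20,)))
    density: float = 0.1
    norm: str = "euclidean"
    max_samples: int = 5000
    theiler_ms: float = 25.0


@dataclass
class SyncResult:
    """The three recurrence-based synchronization measures for one pair."""

    cpr_pearson: float
    cpr_spearman: float
    hellinger: float
    theiler_ms: float
    tau_ms_range: tuple[float, float]


def apply_theiler(rr: TauRecurrenceSeries, window_ms: float) -> TauRecurrenceSeries:
    """Drop all entries with lag τ·dt < window_ms."""
    if window_ms < 0:
        raise ValueError("Theiler window must be non-negative")
    keep = rr.tau_ms >= window_ms
    if not np.any(keep):
        raise ValueError("Theiler window removes the entire RR(tau) series")
    return TauRecurrenceSeries(rr.tau[keep], rr.rr[keep], rr.dt)


def _truncated_pair(
    rr1: TauRecurrenceSeries, rr2: TauRecurrenceSeries, theiler_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    if len(rr1) != len(rr2) or rr1.dt != rr2.dt:
        raise ValueError("RR(tau) series must share one tau grid")
    a = apply_theiler(rr1, theiler_ms)
    b = apply_theiler(rr2, theiler_ms)
    return a.rr, b.rr


def cpr_pearson(
    rr1: TauRecurrenceSeries, rr2: TauRecurrenceSeries, theiler_ms: float = 0.0
) -> float:
    """Pearson correlation of two RR(τ) series beyond the Theiler window."""
    a, b = _truncated_pair(rr1, rr2, theiler_ms)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("CPR undefined for a constant RR(tau) series")
    return float(np.corrcoef(a, b)[0, 1])


def cpr_spearman(
    rr1: TauRecurrenceSeries, rr2: TauRecurrenceSeries, theiler_ms: float = 0.0
) -> float:
    """Spearman (rank) correlation of two RR(τ) series beyond the Theiler
    window; ties receive average ranks."""
    a, b = _truncated_pair(rr1, rr2, theiler_ms)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("CPR undefined for a constant RR(tau) series")
    return float(stats.spearmanr(a, b).statistic)


def hellinger(
    rr1: TauRecurrenceSeries,
    rr2: TauRecurrenceSeries,
    theiler_ms: float = 0.0,
    normalization: str = "unit_sum",
) -> float:
    """Hellinger distance between RR(τ) series viewed as distributions.

    With the default ``unit_sum`` normalization each truncated series is
    scaled to sum to one and H = √(½ Σ (√p − √q)²) ∈ [0, 1]: 0 for
    identical series, 1 for disjoint recurrence-lag distributions.  The
    ``rms`` variant skips the normalization and averages instead of
    summing, H = √(½ · mean((√RR1 − √RR2)²)) — a per-lag root-mean-square
    reading of the same square-root distance.
    """
    a, b = _truncated_pair(rr1, rr2, theiler_ms)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("RR(tau) values must be non-negative")
    if normalization == "rms":
        return float(np.sqrt(0.5 * np.mean((np.sqrt(a) - np.sqrt(b)) ** 2)))
    if normalization != "unit_sum":
        raise ValueError("normalization must be 'unit_sum' or 'rms'")
    sa, sb = a.sum(), b.sum()
    if sa == 0.0 or sb == 0.0:
        raise ValueError("all-zero RR(tau) series after the Theiler window")
    p, q = a / sa, b / sb
    return float(np.sqrt(0.5 * np.sum((np.sqrt(p) - np.sqrt(q)) ** 2)))


def sync_measures(
    rr1: TauRecurrenceSeries, rr2: TauRecurrenceSeries, theiler_ms: float = 25.0
) -> SyncResult:
    """All three measures on a common Theiler-truncated τ grid."""
    a = apply_theiler(rr1, theiler_ms)
    return SyncResult(
        cpr_pearson=cpr_pearson(rr1, rr2, theiler_ms),
        cpr_spearman=cpr_spearman(rr1, rr2, theiler_ms),
        hellinger=hellinger(rr1, rr2, theiler_ms),
        theiler_ms=theiler_ms,
        tau_ms_range=(float(a.tau_ms[0]), float(a.tau_ms[-1])),
    )


def block_shuffle(
    series: np.ndarray,
    n_blocks: int = 5,
    rng: np.random.Generator | None = None,
    mode: str = "equal",
) -> np.ndarray:
    """Surrogate series: contiguous blocks concatenated in random order.

    ``mode="equal"`` (default) cuts equal-width blocks — the value multiset
    of the block-aligned part of the series is preserved exactly, and a
    trailing remainder of fewer than block-width samples is dropped.
    ``mode="random_cuts"`` places the n_blocks−1 cut points uniformly at
    random instead (unequal blocks, full series preserved).  In both modes
    the block-order permutation is forced to differ from the identity.
    """
    x = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least two blocks for a non-identity shuffle")
    if n_blocks > x.size:
        raise ValueError("more blocks than samples")
    rng = rng or np.random.default_rng()
    perm = rng.permutation(n_blocks)
    while np.all(perm == np.arange(n_blocks)):
        perm = rng.permutation(n_blocks)
    if mode == "equal":
        width = x.size // n_blocks
        blocks = [x[i * width : (i + 1) * width] for i in range(n_blocks)]
    elif mode == "random_cuts":
        cuts = np.sort(rng.choice(np.arange(1, x.size), n_blocks - 1, replace=False))
        blocks = np.split(x, cuts)
    else:
        raise ValueError("mode must be 'equal' or 'random_cuts'")
    return np.concatenate([blocks[i] for i in perm])


def surrogate_confidence_limit(
    v1: np.ndarray,
    v2: np.ndarray,
    dt: float,
    pipeline: RecurrencePipelineConfig | None = None,
    *,
    n_surrogates: int = 1000,
    n_blocks: int = 5,
    quantile: float = 0.95,
    rng: np.random.Generator | int | None = None,
    shuffle_second: bool = True,
) -> tuple[float, np.ndarray]:
    """Null distribution p(H) from block-shuffle surrogates and its quantile.

    One voltage series (the second by default) is block-shuffled and pushed
    through the full recurrence pipeline for every surrogate; H is computed
    against the unshuffled partner's RR(τ).  Both series are decimated to
    the pipeline rate first (so every surrogate shares the original τ grid)
    and truncated to a whole number of blocks.  Returns (H quantile, all
    surrogate H values).  H of the original pair below the returned limit
    indicates phase synchronization at the chosen confidence level.
    """
    import warnings

    from .recurrence import decimate_series, delay_embed, threshold_for_density, tau_recurrence_rate_streaming

    pipeline = pipeline or RecurrencePipelineConfig()
    if n_surrogates < 100:
        warnings.warn("fewer than 100 surrogates: quantile estimate is coarse")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fixed, shuffled = (v1, v2) if shuffle_second else (v2, v1)
    xf, dt_eff, _ = decimate_series(np.asarray(fixed, float), dt, pipeline.max_samples)
    xs, _, _ = decimate_series(np.asarray(shuffled, float), dt, pipeline.max_samples)
    n = min(xf.size, xs.size)
    n = (n // n_blocks) * n_blocks
    xf, xs = xf[:n], xs[:n]

    def _rr(x: np.ndarray) -> TauRecurrenceSeries:
        X = delay_embed(x, pipeline.embedding)
        eps = threshold_for_density(X, pipeline.density, pipeline.norm)
        return tau_recurrence_rate_streaming(X, eps, pipeline.norm, dt_eff)

    rr_fixed = _rr(xf)
    hs = np.empty(n_surrogates)
    for k in range(n_surrogates):
        hs[k] = hellinger(rr_fixed, _rr(block_shuffle(xs, n_blocks, rng)), pipeline.theiler_ms)
    return float(np.quantile(hs, quantile)), hs


def synchronization_scan(
    cfg: CoupledConfig,
    g_grid: np.ndarray,
    pipeline: RecurrencePipelineConfig | None = None,
    *,
    dt: float = 0.05,
    n_steps: int = 50_000,
    transient_steps: int = 10_000,
    measures: tuple[str, ...] = ("delta_omega", "cpr_p", "cpr_s", "hellinger"),
) -> pd.DataFrame:
    """Per-coupling-strength synchronization measures for a coupled pair.

    Integrates the pair once for the whole (sorted) g grid as a vectorized
    batch, then computes the Hilbert mean-frequency mismatch and, when
    requested, the recurrence-based measures for each g.  Deterministic for
    a fixed configuration.
    """
    g_grid = np.asarray(g_grid, dtype=float)
    pipeline = pipeline or RecurrencePipelineConfig()
    from dataclasses import replace

    traj = simulate_coupled(
        replace(cfg, g=g_grid), dt=dt, n_steps=n_steps,
        transient_steps=transient_steps, store_w=False,
    )
    out: dict[str, np.ndarray] = {"g": g_grid}
    if "delta_omega" in measures:
        out["delta_omega"] = np.asarray(frequency_mismatch(traj.t, traj.v1, traj.v2))
    rec_cols = [m for m in ("cpr_p", "cpr_s", "hellinger") if m in measures]
    if rec_cols:
        vals = {m: np.empty(g_grid.size) for m in rec_cols}
        for j in range(g_grid.size):
            rr1 = rr_tau_pipeline(
                traj.v1[:, j], dt, embedding=pipeline.embedding,
                density=pipeline.density, norm=pipeline.norm,
                max_samples=pipeline.max_samples,
            )
            rr2 = rr_tau_pipeline(
                traj.v2[:, j], dt, embedding=pipeline.embedding,
                density=pipeline.density, norm=pipeline.norm,
                max_samples=pipeline.max_samples,
            )
            if "cpr_p" in vals:
                vals["cpr_p"][j] = cpr_pearson(rr1, rr2, pipeline.theiler_ms)
            if "cpr_s" in vals:
                vals["cpr_s"][j] = cpr_spearman(rr1, rr2, pipeline.theiler_ms)
            if "hellinger" in vals:
                vals["hellinger"][j] = hellinger(rr1, rr2, pipeline.theiler_ms)
        out.update(vals)
    return pd.DataFrame(out)


def sync_onset(
    g: np.ndarray,
    values: np.ndarray,
    threshold: float,
    direction: str = "above",
) -> float | None:
    """Smallest g after which values stay above (or below) threshold.

    Mirrors the frequency-locking onset: the criterion must hold for every
    larger g on the grid.  Returns None when never sustained.
    """
    g = np.asarray(g, float)
    v = np.asarray(values, float)
    ok = v > threshold if direction == "above" else v < threshold
    if not ok[-1]:
        return None
    bad = np.flatnonzero(~ok)
    if bad.size == 0:
        return float(g[0])
    if bad[-1] == len(g) - 1:
        return None
    return float(g[bad[-1] + 1])
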