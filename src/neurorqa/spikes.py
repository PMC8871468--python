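"""Spike extraction, regime classification and Hilbert-phase frequency tools.

Spikes are detected as upward threshold crossings of the membrane voltage
(the Morris–Lecar action potential robustly overshoots 0 mV), with a short
refractory gap suppressing double counts on noisy flanks.  Regimes are
classified from stationary interspike intervals (ISIs): an *n*-spike burster
fires exactly *n* action potentials in every stimulus period; an aperiodic
(chaotic) response shows many distinct ISIs with no repeating pattern.

Phases of spiky chaotic signals are estimated with the analytic-signal
(Hilbert-transform) phase; individual instantaneous frequencies are
unreliable for such signals, but the long-run mean frequency Ω is a robust
average and the mismatch ΔΩ = Ω1 − Ω2 between two coupled neurons detects
frequency locking (ΔΩ → 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .model import EFStimulus, MLParams, simulate_single

__all__ = [
    "SpikeTrain",
    "PhaseSeries",
    "RegimeLabel",
    "detect_spikes",
    "interspike_intervals",
    "spikes_per_period",
    "classify_regime",
    "bifurcation_scan",
    "hilbert_phase",
    "mean_frequency",
    "frequency_mismatch",
    "locking_onset",
]


@dataclass
class SpikeTrain:
    """Strictly increasing spike times (ms) with the detector settings used."""

    times: np.ndarray
    threshold: float = 0.0
    refractory: float = 2.0

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PhaseSeries:
    """Unwrapped instantaneous phase φ(t) (rad) of one voltage channel."""

    t: np.ndarray
    phi: np.ndarray
    source: str = "v"


@dataclass
class RegimeLabel:
    """Firing-regime classification with its supporting statistics.

    ``kind`` is one of ``n_spike_bursting``, ``one_to_one``, ``chaotic``,
    ``mode_locked``; ``n`` the spikes per stimulus period where defined.
    """

    kind: str
    n: int | None = None
    distinct_isi_count: int = 0
    spikes_per_period: int | None = None
    periods_agree: bool = False


def detect_spikes(
    t: np.ndarray,
    v: np.ndarray,
    threshold: float = 0.0,
    refractory: float = 2.0,
) -> SpikeTrain:
    """Detect spikes as upward crossings of ``threshold``.

    The spike time is the first sample at or above threshold of each upward
    crossing; crossings closer than ``refractory`` ms to the previous
    accepted spike are suppressed.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("voltage series must be non-empty and finite")
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    times = []
    last = -np.inf
    for i in up:
        if t[i] - last >= refractory:
            times.append(t[i])
            last = t[i]
    return SpikeTrain(np.asarray(times, float), threshold, refractory)


def interspike_intervals(st: SpikeTrain) -> np.ndarray:
    """First differences of the spike times; requires at least two spikes."""
    if len(st) < 2:
        raise ValueError("need at least two spikes to form intervals")
    return np.diff(st.times)


def spikes_per_period(
    st: SpikeTrain,
    omega: float,
    t_start: float,
    t_end: float,
) -> tuple[int, np.ndarray, bool]:
    """Spike count per stimulus period 2π/ω inside [t_start, t_end].

    Returns (modal count, per-period counts, all-periods-agree flag).  The
    window must cover at least five full periods.
    """
    period = 2.0 * np.pi / omega
    n_periods = int(np.floor((t_end - t_start) / period))
    if n_periods < 5:
        raise ValueError("window must cover at least 5 stimulus periods")
    edges = t_start + period * np.arange(n_periods + 1)
    counts = np.histogram(st.times, bins=edges)[0]
    if counts.size == 0 or len(st) == 0:
        return 0, counts, True
    vals, freq = np.unique(counts, return_counts=True)
    modal = int(vals[np.argmax(freq)])
    return modal, counts, bool(np.all(counts == modal))


def _repetition_period(isis: np.ndarray, tol: float, max_period: int = 12) -> int | None:
    """Smallest P with isi[i] ≈ isi[i+P] for all i, or None."""
    for P in range(1, min(max_period, len(isis) - 1) + 1):
        if np.all(np.abs(isis[P:] - isis[:-P]) <= tol):
            return P
    return None


def classify_regime(
    isis: np.ndarray,
    spikes_per_period_stats: tuple[int, np.ndarray, bool] | None = None,
    *,
    isi_round: float = 0.5,
    distinct_threshold: int = 10,
    repeat_tol: float = 0.5,
) -> RegimeLabel:
    """Classify a stationary ISI sequence into a firing regime.

    Periodic *n*-spike bursting requires agreeing per-period counts and a
    repeating ISI pattern; an aperiodic (chaotic) label requires more than
    ``distinct_threshold`` distinct ISIs (rounded to ``isi_round`` ms) with
    no repetition period; anything else is mode-locked.
    """
    isis = np.asarray(isis, float)
    if isis.size < 2:
        raise ValueError("stationary window too short: need >= 2 intervals")
    distinct = len(np.unique(np.round(isis / isi_round) * isi_round))
    P = _repetition_period(isis, repeat_tol)
    n, counts, agree = (None, None, False)
    if spikes_per_period_stats is not None:
        n, counts, agree = spikes_per_period_stats
    if spikes_per_period_stats is not None and agree and P is not None:
        kind = "one_to_one" if n == 1 else "n_spike_bursting"
        return RegimeLabel(kind, n, distinct, n, True)
    if P is None and distinct > distinct_threshold:
        return RegimeLabel("chaotic", None, distinct, n, bool(agree))
    if P is not None and spikes_per_period_stats is None:
        return RegimeLabel("n_spike_bursting", P if P > 1 else 1, distinct, n, bool(agree))
    return RegimeLabel("mode_locked", None, distinct, n, bool(agree))


def stationary_window(t: np.ndarray, fraction: float = 0.25) -> tuple[float, float]:
    """Analysis window skipping the leading ``fraction`` of the run as transient."""
    t0 = float(t[0] + fraction * (t[-1] - t[0]))
    return t0, float(t[-1])


def bifurcation_scan(
    omegas: np.ndarray,
    *,
    params: MLParams | None = None,
    A: float = 0.1,
    VE: float = -17.63,
    dt: float = 0.01,
    t_total: float = 2000.0,
    transient_fraction: float = 0.25,
    isi_cap: float = 250.0,
) -> pd.DataFrame:
    """Stationary ISIs for each stimulus frequency (long-format table).

    Integrates the forced neuron for each ω in one vectorized batch, discards
    the leading ``transient_fraction`` of each run and emits one row per
    stationary interspike interval, capped at ``isi_cap`` ms.
    """
    omegas = np.atleast_1d(np.asarray(omegas, float))
    params = params or MLParams()
    traj = simulate_single(
        params, EFStimulus(A=A, omega=omegas, VE=VE), dt=dt, t_total=t_total
    )
    t0, t1 = stationary_window(traj.t, transient_fraction)
    rows: list[tuple[float, float]] = []
    for j, om in enumerate(omegas):
        st = detect_spikes(traj.t, traj.v[:, j])
        keep = st.times[(st.times >= t0) & (st.times <= t1)]
        if keep.size >= 2:
            for isi in np.diff(keep):
                if isi <= isi_cap:
                    rows.append((float(om), float(isi)))
    return pd.DataFrame(rows, columns=["omega", "isi"])


def hilbert_phase(t: np.ndarray, v: np.ndarray, source: str = "v") -> PhaseSeries:
    """Unwrapped analytic-signal phase of a (mean-subtracted) voltage series.

    Accepts a 1-D series or a 2-D array with channels along the second axis.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    if v.shape[0] < 64:
        raise ValueError("series too short for a stable analytic signal")
    centered = v - v.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValueError("phase undefined for a constant series")
    analytic = hilbert(centered, axis=0)
    phi = np.unwrap(np.angle(analytic), axis=0)
    return PhaseSeries(t=t, phi=phi, source=source)


def mean_frequency(ph: PhaseSeries, edge_fraction: float = 0.1) -> float | np.ndarray:
    """Mean frequency Ω = Δφ/Δt (rad/ms) over the series, edges trimmed.

    The analytic signal is unreliable near the ends of a finite record, so a
    fraction of samples at each edge is excluded from the average.
    """
    n = ph.phi.shape[0]
    i0 = int(np.floor(edge_fraction * n))
    i1 = n - 1 - i0
    if i1 <= i0:
        raise ValueError("series too short for the requested edge trim")
    om = (ph.phi[i1] - ph.phi[i0]) / (ph.t[i1] - ph.t[i0])
    return om if np.ndim(om) else float(om)


def frequency_mismatch(t: np.ndarray, v1: np.ndarray, v2: np.ndarray) -> float | np.ndarray:
    """ΔΩ = Ω1 − Ω2 (rad/ms) from the Hilbert phases of two voltage channels."""
    om1 = mean_frequency(hilbert_phase(t, v1, "v1"))
    om2 = mean_frequency(hilbert_phase(t, v2, "v2"))
    return om1 - om2


def locking_onset(
    g: np.ndarray,
    delta_omega: np.ndarray,
    tolerance: float | None = None,
) -> float | None:
    """Smallest grid value after which |ΔΩ| stays below tolerance.

    The default tolerance is 2% of |ΔΩ| at the first grid point (the
    uncoupled mismatch).  Returns None when locking is never sustained.
    """
    g = np.asarray(g, float)
    dom = np.abs(np.asarray(delta_omega, float))
    if np.any(np.diff(g) < 0):
        raise ValueError("grid must be sorted ascending")
    if tolerance is None:
        tolerance = 0.02 * dom[0]
    below = dom < tolerance
    if not below[-1]:
        return None
    # last index where the criterion fails, onset is the next grid point
    above = np.flatnonzero(~below)
    if above.size == 0:
        return float(g[0])
    if above[-1] == len(g) - 1:
        return None
    return float(g[above[-1] + 1])
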