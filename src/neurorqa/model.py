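"""Morris–Lecar neuron dynamics under a sinusoidal ELF electric field.

The membrane model is the two-variable Morris–Lecar system: a fast voltage
``v`` (mV) driven by a fast inward current, a slow outward (potassium-like)
current gated by the recovery variable ``w``, and a leak.  An extremely-low-
frequency (ELF) sinusoidal electric field does not enter as a current source;
it induces a membrane depolarization ``Δv(t) = (A/ω)·sin(ωt) + VE`` that is
added to the voltage inside every ionic driving force, and its time
derivative ``A·cos(ωt)`` enters the current balance.

Two neurons may be coupled through a gap junction, modelled as the ohmic
current ``−g·(v_i − v_j)`` in each voltage equation.

All rates are per millisecond, voltages in mV, conductances in mS/cm²,
capacitance in μF/cm², angular frequency ``ω`` in rad/ms.

Every function broadcasts over trailing batch axes, so parameter sweeps
(e.g. a grid of coupling strengths) integrate as a single vectorized run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "MLParams",
    "EFStimulus",
    "NeuronState",
    "CoupledConfig",
    "Trajectory",
    "CoupledTrajectory",
    "DivergenceError",
    "m1_steady",
    "m2_steady",
    "b_timescale",
    "delta_v",
    "delta_v_dot",
    "single_neuron_derivatives",
    "coupled_derivatives",
    "make_single_rhs",
    "make_coupled_rhs",
    "rk4_step",
    "integrate",
    "simulate_single",
    "simulate_coupled",
]


class DivergenceError(RuntimeError):
    """Raised when an integrated voltage leaves the physiological range."""


@dataclass(frozen=True)
class MLParams:
    """Morris–Lecar membrane parameters.

    Defaults are the cortical-neuron set used throughout the package:
    ``u1, u2`` midpoint/slope of the fast (Na-like) activation sigmoid,
    ``u3, u4`` midpoint/slope of the slow (K-like) activation, maximal
    conductances ``gfast/gslow/gleak``, reversal potentials, recovery rate
    constant ``phi``, capacitance ``c`` and a constant stimulus current
    ``istim`` (zero: the neuron is driven only by the field).
    """

    u1: float = -1.2
    u2: float = 18.0
    u3: float = -13.0
    u4: float = 10.0
    gfast: float = 20.0
    gslow: float = 20.0
    gleak: float = 2.0
    eNa: float = 50.0
    eK: float = -100.0
    eleak: float = -70.0
    phi: float = 0.15
    c: float = 2.0
    istim: float = 0.0

    def __post_init__(self) -> None:
        if self.u2 == 0.0 or self.u4 == 0.0:
            raise ValueError("slope factors u2 and u4 must be nonzero")
        if min(self.gfast, self.gslow, self.gleak) < 0.0:
            raise ValueError("conductances must be non-negative")
        if self.c <= 0.0:
            raise ValueError("membrane capacitance c must be positive")


@dataclass(frozen=True)
class EFStimulus:
    """Sinusoidal ELF field inducing the depolarization Δv(t)=(A/ω)sin(ωt)+VE.

    ``A`` is the field amplitude (enters Δv scaled by 1/ω), ``omega`` the
    angular frequency in rad/ms and ``VE`` a direct voltage offset in mV.
    ``A`` and ``omega`` may be arrays for vectorized sweeps.
    """

    A: float | np.ndarray = 0.1
    omega: float | np.ndarray = 0.286
    VE: float = -17.63

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        om = np.asarray(self.omega, dtype=float)
        if np.any((A != 0.0) & (om <= 0.0)):
            raise ValueError("omega must be positive wherever A is nonzero")


@dataclass(frozen=True)
class NeuronState:
    """Instantaneous state: membrane voltage v (mV), recovery variable w."""

    v: float
    w: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.v) and np.isfinite(self.w)):
            raise ValueError("neuron state must be finite")


@dataclass(frozen=True)
class CoupledConfig:
    """Gap-junction-coupled pair: two parameter sets, coupling g, shared field.

    ``g`` may be an array to integrate a whole coupling sweep in one batch.
    ``field_term_over_c=False`` moves the −dΔv/dt term outside the 1/c
    factor (an alternative reading of the current balance).
    """

    params1: MLParams = field(default_factory=MLParams)
    params2: MLParams = field(default_factory=MLParams)
    g: float | np.ndarray = 0.0
    stimulus: EFStimulus = field(default_factory=lambda: EFStimulus(A=0.0))
    v1_0: float = -65.6
    v2_0: float = -60.0
    w1_0: float = 0.0
    w2_0: float = 0.0
    field_term_over_c: bool = True

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.g, dtype=float) < 0.0):
            raise ValueError("gap-junction conductance g must be non-negative")


@dataclass
class Trajectory:
    """Uniformly sampled (t, v, w) series from a single-neuron integration."""

    t: np.ndarray
    v: np.ndarray
    w: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class CoupledTrajectory:
    """Uniformly sampled series of a coupled pair; w channels optional."""

    t: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    w1: np.ndarray | None = None
    w2: np.ndarray | None = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


# ---------------------------------------------------------------------------
# gating steady states and field drive


def m1_steady(v, p: MLParams):
    """Fast-current activation steady state, 0.5·(1 + tanh((v−u1)/u2)) ∈ [0,1]."""
    return 0.5 * (1.0 + np.tanh((v - p.u1) / p.u2))


def m2_steady(v, p: MLParams):
    """Slow-current activation steady state, 0.5·(1 + tanh((v−u3)/u4)) ∈ [0,1]."""
    return 0.5 * (1.0 + np.tanh((v - p.u3) / p.u4))


def b_timescale(v, p: MLParams):
    """Voltage-dependent time-constant factor 1/cosh((v−u3)/(2·u4)) ∈ (0,1]."""
    return 1.0 / np.cosh((v - p.u3) / (2.0 * p.u4))


def delta_v(t, s: EFStimulus):
    """Field-induced depolarization Δv(t) = (A/ω)·sin(ωt) + VE (mV).

    For A = 0 the field reduces to the constant offset VE regardless of ω.
    """
    A = np.asarray(s.A, dtype=float)
    om = np.asarray(s.omega, dtype=float)
    t = np.asarray(t, dtype=float)
    om_safe = np.where(om > 0.0, om, 1.0)
    out = np.where(A == 0.0, s.VE, (A / om_safe) * np.sin(om * t) + s.VE)
    return out[()] if out.ndim == 0 else out


def delta_v_dot(t, s: EFStimulus):
    """Time derivative dΔv/dt = A·cos(ωt) (mV/ms)."""
    A = np.asarray(s.A, dtype=float)
    om = np.asarray(s.omega, dtype=float)
    t = np.asarray(t, dtype=float)
    out = np.where(A == 0.0, 0.0, A * np.cos(om * t))
    return out[()] if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# vector fields


def _membrane_rhs(v, w, dv_field, ddv_field, p: MLParams, over_c: bool):
    """Shared current balance for one membrane; broadcasts over batch axes."""
    m1 = 0.5 * (1.0 + np.tanh((v - p.u1) / p.u2))
    m2 = 0.5 * (1.0 + np.tanh((v - p.u3) / p.u4))
    cosh_b = np.cosh((v - p.u3) / (2.0 * p.u4))  # 1/b(v)
    vd = v + dv_field
    i_ion = (
        p.gfast * m1 * (vd - p.eNa)
        + p.gslow * w * (vd - p.eK)
        + p.gleak * (vd - p.eleak)
    )
    if over_c:
        dv = (p.istim - ddv_field - i_ion) / p.c
    else:
        dv = (p.istim - i_ion) / p.c - ddv_field
    dw = p.phi * (m2 - w) * cosh_b
    return dv, dw


def make_single_rhs(
    p: MLParams, s: EFStimulus, field_term_over_c: bool = True
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the RHS f(t, y) of the forced single neuron, y = (v, w)."""

    def rhs(t, y):
        dv, dw = _membrane_rhs(
            y[0], y[1], delta_v(t, s), delta_v_dot(t, s), p, field_term_over_c
        )
        return np.stack(np.broadcast_arrays(dv, dw))

    return rhs


def make_coupled_rhs(cfg: CoupledConfig) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the RHS of the gap-junction pair, y = (v1, w1, v2, w2)."""
    g = np.asarray(cfg.g, dtype=float)
    s = cfg.stimulus

    def rhs(t, y):
        v1, w1, v2, w2 = y[0], y[1], y[2], y[3]
        dvf = delta_v(t, s)
        ddvf = delta_v_dot(t, s)
        dv1, dw1 = _membrane_rhs(v1, w1, dvf, ddvf, cfg.params1, cfg.field_term_over_c)
        dv2, dw2 = _membrane_rhs(v2, w2, dvf, ddvf, cfg.params2, cfg.field_term_over_c)
        gap1 = g * (v1 - v2)
        dv1 = dv1 - gap1 / cfg.params1.c
        dv2 = dv2 + gap1 / cfg.params2.c
        return np.stack(np.broadcast_arrays(dv1, dw1, dv2, dw2))

    return rhs


def single_neuron_derivatives(
    state,
    t: float,
    p: MLParams,
    s: EFStimulus,
    field_term_over_c: bool = True,
) -> np.ndarray:
    """Evaluate (dv/dt, dw/dt) of the forced neuron at one state and time."""
    y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("state must be finite")
    return make_single_rhs(p, s, field_term_over_c)(t, y)


def coupled_derivatives(state, t: float, cfg: CoupledConfig) -> np.ndarray:
    """Evaluate (dv1, dw1, dv2, dw2)/dt of the coupled pair."""
    y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("state must be finite")
    return make_coupled_rhs(cfg)(t, y)


# ---------------------------------------------------------------------------
# fixed-step integration


def rk4_step(rhs, t, y, dt):
    """One classic 4th-order Runge–Kutta step."""
    k1 = rhs(t, y)
    k2 = rhs(t + 0.5 * dt, y + 0.5 * dt * k1)
    k3 = rhs(t + 0.5 * dt, y + 0.5 * dt * k2)
    k4 = rhs(t + dt, y + dt * k3)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate(
    rhs,
    y0,
    dt: float,
    n_steps: int,
    transient_steps: int = 0,
    t0: float = 0.0,
    divergence_bound: float = 500.0,
    store: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate dy/dt = rhs(t, y) with fixed-step RK4.

    Parameters
    ----------
    y0
        Initial state, shape ``(d,)`` or ``(d, *batch)``.
    n_steps, transient_steps
        Total number of RK4 steps; the first ``transient_steps`` samples are
        dropped from the returned arrays (the state at step ``transient_steps``
        is the first kept sample).
    divergence_bound
        Any stored component exceeding this magnitude (or becoming non-finite)
        raises :class:`DivergenceError` naming the offending step.
    store
        Optional component indices to record (saves memory on large sweeps).

    Returns
    -------
    (t, Y)
        ``t`` of length ``n_steps − transient_steps + 1``;
        ``Y`` of shape ``(len(t), d_store, *batch)``.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    if not (n_steps > transient_steps >= 0):
        raise ValueError("need n_steps > transient_steps >= 0")
    y = np.array(y0, dtype=float)
    idx = list(range(y.shape[0])) if store is None else list(store)
    n_keep = n_steps - transient_steps + 1
    out = np.empty((n_keep,) + (len(idx),) + y.shape[1:], dtype=float)
    if transient_steps == 0:
        out[0] = y[idx]
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(1, n_steps + 1):
            y = rk4_step(rhs, t0 + (i - 1) * dt, y, dt)
            if i >= transient_steps:
                out[i - transient_steps] = y[idx]
    bad = ~np.isfinite(out) | (np.abs(out) > divergence_bound)
    if bad.any():
        first = int(np.argwhere(bad.reshape(n_keep, -1).any(axis=1))[0, 0])
        raise DivergenceError(
            f"state exceeded |y| = {divergence_bound} (or became non-finite) "
            f"at step {transient_steps + first}"
        )
    t = t0 + dt * np.arange(transient_steps, n_steps + 1)
    return t, out


def simulate_single(
    p: MLParams | None = None,
    s: EFStimulus | None = None,
    *,
    v0: float = -65.0,
    w0: float = 0.0,
    dt: float = 0.01,
    t_total: float = 2000.0,
    transient_steps: int = 0,
    field_term_over_c: bool = True,
) -> Trajectory:
    """Integrate the forced single neuron from rest; defaults give a 2000 ms run."""
    p = p or MLParams()
    s = s or EFStimulus()
    n_steps = int(round(t_total / dt))
    # broadcast v0/w0 against any batch axes carried by the stimulus
    batch = np.broadcast_shapes(
        np.shape(v0), np.shape(w0), np.shape(s.A), np.shape(s.omega)
    )
    y_init = np.empty((2,) + batch, dtype=float)
    y_init[0] = v0
    y_init[1] = w0
    t, Y = integrate(
        make_single_rhs(p, s, field_term_over_c),
        y_init,
        dt,
        n_steps,
        transient_steps,
    )
    return Trajectory(t=t, v=Y[:, 0], w=Y[:, 1])


def simulate_coupled(
    cfg: CoupledConfig,
    *,
    dt: float = 0.05,
    n_steps: int = 50_000,
    transient_steps: int = 10_000,
    store_w: bool = True,
) -> CoupledTrajectory:
    """Integrate the gap-junction pair; defaults give a 2500 ms run with the
    first 10,000 samples discarded as transient.

    ``cfg.g`` may be an array: the whole coupling grid integrates in one batch
    and the returned voltage arrays gain a trailing grid axis.
    """
    batch = np.broadcast_shapes(np.shape(cfg.g), np.shape(cfg.stimulus.A))
    y0 = np.empty((4,) + batch, dtype=float)
    y0[0] = cfg.v1_0
    y0[1] = cfg.w1_0
    y0[2] = cfg.v2_0
    y0[3] = cfg.w2_0
    store = None if store_w else [0, 2]
    t, Y = integrate(make_coupled_rhs(cfg), y0, dt, n_steps, transient_steps, store=store)
    if store_w:
        return CoupledTrajectory(t=t, v1=Y[:, 0], v2=Y[:, 2], w1=Y[:, 1], w2=Y[:, 3])
    return CoupledTrajectory(t=t, v1=Y[:, 0], v2=Y[:, 1])
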