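"""Experiment configuration, runners and file I/O.

One structured YAML config drives every experiment; unknown keys are
rejected at load time with a message naming the offending key.  Runners
return in-memory results and, when given an output directory, write
delimited-text tables (header row, ``#`` comment lines carrying metadata),
an ``.npz`` array container for trajectories, and a JSON run record with a
config hash and seed so reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import (
    CoupledConfig,
    CoupledTrajectory,
    EFStimulus,
    MLParams,
    Trajectory,
    simulate_coupled,
    simulate_single,
)
from .recurrence import (
    EMBEDDING_PRESETS,
    EmbeddingSpec,
    RecurrencePlot,
    decimate_series,
    delay_embed,
    recurrence_matrix,
    tau_recurrence_rate_streaming,
    threshold_for_density,
)
from .spikes import (
    RegimeLabel,
    SpikeTrain,
    bifurcation_scan,
    classify_regime,
    detect_spikes,
    frequency_mismatch,
    spikes_per_period,
    stationary_window,
)
from .sync import (
    RecurrencePipelineConfig,
    surrogate_confidence_limit,
    synchronization_scan,
)

__all__ = [
    "ExperimentConfig",
    "load_config",
    "write_table",
    "read_table",
    "save_trajectory",
    "load_trajectory",
    "export_rp_coordinates",
    "read_rp_coordinates",
    "run_single_neuron",
    "run_bifurcation",
    "run_g_sweep",
    "run_amplitude_sweep",
    "run_surrogate_test",
    "export_rp",
]

_FLOAT_FMT = "%.8e"  # nine significant digits, byte-stable


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class IntegrationConfig:
    dt: float = 0.05
    n_steps: int = 50_000
    transient_steps: int = 10_000
    t_total: float = 2000.0      # single-neuron runs (dt 0.01)
    dt_single: float = 0.01
    v0: float = -65.0
    w0: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt_single <= 0:
            raise ValueError("integration.dt must be positive")
        if not (self.n_steps > self.transient_steps >= 0):
            raise ValueError("integration.n_steps must exceed transient_steps")


@dataclass(frozen=True)
class RecurrenceConfig:
    preset: str = "chaos"
    dimension: int | None = None
    delays: tuple[int, ...] | None = None
    density: float = 0.1
    norm: str = "euclidean"
    max_samples: int = 5000

    def embedding(self) -> EmbeddingSpec:
        if self.dimension is not None:
            return EmbeddingSpec(self.dimension, tuple(self.delays or ()))
        if self.preset not in EMBEDDING_PRESETS:
            raise ValueError(f"unknown embedding preset {self.preset!r}")
        return EMBEDDING_PRESETS[self.preset]

    def __post_init__(self) -> None:
        if not 0.0 < self.density <= 1.0:
            raise ValueError("recurrence.density must be in (0, 1]")
        self.embedding()


@dataclass(frozen=True)
class SyncConfig:
    theiler_ms: float = 25.0
    n_surrogates: int = 1000
    n_blocks: int = 5
    quantile: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("sync.n_blocks must be >= 2")
        if not 0.0 < self.quantile <= 1.0:
            raise ValueError("sync.quantile must be in (0, 1]")


@dataclass(frozen=True)
class SweepConfig:
    variable: str = "g"
    start: float = 0.0
    stop: float = 0.15
    num: int = 500

    def grid(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.num)

    def __post_init__(self) -> None:
        if self.variable not in ("g", "A", "omega"):
            raise ValueError("sweep.variable must be one of g, A, omega")
        if self.num < 1 or self.stop < self.start:
            raise ValueError("sweep grid must be non-empty and ascending")


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated experiment description (model, stimulus, integration,
    recurrence, synchronization and sweep sections)."""

    neuron1: MLParams = field(default_factory=lambda: MLParams(u2=18.0, u3=-12.8))
    neuron2: MLParams = field(default_factory=lambda: MLParams(u2=18.1, u3=-10.0))
    g: float = 0.0
    field_term_over_c: bool = True
    v1_0: float = -65.6
    v2_0: float = -60.0
    w1_0: float = 0.0
    w2_0: float = 0.0
    stimulus: EFStimulus = field(default_factory=lambda: EFStimulus(A=0.0))
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    recurrence: RecurrenceConfig = field(default_factory=RecurrenceConfig)
    sync: SyncConfig = field(default_factory=SyncConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)

    def coupled(self, g: float | np.ndarray | None = None) -> CoupledConfig:
        return CoupledConfig(
            params1=self.neuron1,
            params2=self.neuron2,
            g=self.g if g is None else g,
            stimulus=self.stimulus,
            v1_0=self.v1_0,
            v2_0=self.v2_0,
            w1_0=self.w1_0,
            w2_0=self.w2_0,
            field_term_over_c=self.field_term_over_c,
        )

    def pipeline(self) -> RecurrencePipelineConfig:
        return RecurrencePipelineConfig(
            embedding=self.recurrence.embedding(),
            density=self.recurrence.density,
            norm=self.recurrence.norm,
            max_samples=self.recurrence.max_samples,
            theiler_ms=self.sync.theiler_ms,
        )


def _build(cls, section: dict, where: str):
    valid = set(cls.__dataclass_fields__)
    for key in section:
        if key not in valid:
            raise ValueError(f"unknown config key {where}.{key!r}")
    if "delays" in section and section["delays"] is not None:
        section = {**section, "delays": tuple(section["delays"])}
    try:
        return cls(**section)
    except ValueError as err:
        raise ValueError(f"invalid config section {where}: {err}") from err


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> ExperimentConfig:
    """Load and validate a YAML experiment config; missing sections take the
    coupled-chaotic-pair defaults.  ``overrides`` is a nested dict applied on
    top (CLI flags)."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for sec, vals in overrides.items():
            raw.setdefault(sec, {}).update(vals)
    known = {"model", "stimulus", "integration", "recurrence", "sync", "sweep"}
    for key in raw:
        if key not in known:
            raise ValueError(f"unknown config section {key!r}")
    model = dict(raw.get("model", {}))
    for key in model:
        if key not in {"neuron1", "neuron2", "g", "field_term_over_c",
                       "v1_0", "v2_0", "w1_0", "w2_0"}:
            raise ValueError(f"unknown config key model.{key!r}")
    kwargs: dict = {}
    defaults = {"neuron1": {"u2": 18.0, "u3": -12.8}, "neuron2": {"u2": 18.1, "u3": -10.0}}
    for neuron in ("neuron1", "neuron2"):
        sec = {**defaults[neuron], **model.get(neuron, {})}
        kwargs[neuron] = _build(MLParams, sec, f"model.{neuron}")
    for key in ("g", "field_term_over_c", "v1_0", "v2_0", "w1_0", "w2_0"):
        if key in model:
            kwargs[key] = model[key]
    kwargs["stimulus"] = _build(EFStimulus, dict(raw.get("stimulus", {"A": 0.0})), "stimulus")
    kwargs["integration"] = _build(IntegrationConfig, dict(raw.get("integration", {})), "integration")
    kwargs["recurrence"] = _build(RecurrenceConfig, dict(raw.get("recurrence", {})), "recurrence")
    kwargs["sync"] = _build(SyncConfig, dict(raw.get("sync", {})), "sync")
    kwargs["sweep"] = _build(SweepConfig, dict(raw.get("sweep", {})), "sweep")
    return ExperimentConfig(**kwargs)


def config_hash(cfg: ExperimentConfig) -> str:
    """Stable hash of the effective configuration."""
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _run_record(cfg: ExperimentConfig, seed: int | None, outputs: list[str]) -> dict:
    return {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": outputs,
    }


# ---------------------------------------------------------------------------
# file I/O


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Delimited text table: '#' metadata comments, header row, 9-digit floats."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def save_trajectory(traj: Trajectory | CoupledTrajectory, path: str | Path) -> None:
    """Compressed binary container (.npz) for a trajectory."""
    arrays = {k: v for k, v in vars(traj).items() if v is not None}
    np.savez_compressed(path, kind=type(traj).__name__, **arrays)


def load_trajectory(path: str | Path) -> Trajectory | CoupledTrajectory:
    with np.load(path) as data:
        kind = str(data["kind"])
        arrays = {k: data[k] for k in data.files if k != "kind"}
    cls = CoupledTrajectory if kind == "CoupledTrajectory" else Trajectory
    return cls(**arrays)


def trajectory_table(traj: Trajectory | CoupledTrajectory) -> pd.DataFrame:
    if isinstance(traj, CoupledTrajectory):
        cols = {"t": traj.t, "v": traj.v1, "v2": traj.v2}
        if traj.w1 is not None:
            cols["w"] = traj.w1
            cols["w2"] = traj.w2
        order = [c for c in ("t", "v", "w", "v2", "w2") if c in cols]
        return pd.DataFrame({c: cols[c] for c in order})
    return pd.DataFrame({"t": traj.t, "v": traj.v, "w": traj.w})


def table_trajectory(df: pd.DataFrame) -> Trajectory | CoupledTrajectory:
    if "v2" in df.columns:
        return CoupledTrajectory(
            t=df["t"].to_numpy(), v1=df["v"].to_numpy(), v2=df["v2"].to_numpy(),
            w1=df["w"].to_numpy() if "w" in df else None,
            w2=df["w2"].to_numpy() if "w2" in df else None,
        )
    return Trajectory(t=df["t"].to_numpy(), v=df["v"].to_numpy(), w=df["w"].to_numpy())


def export_rp_coordinates(rp: RecurrencePlot, path: str | Path) -> None:
    """Coordinate-list text export of a recurrence matrix (i, j of the ones)."""
    i, j = np.nonzero(rp.R)
    emb = rp.embedding
    with Path(path).open("w") as fh:
        fh.write(f"# N = {rp.n}\n# epsilon = {rp.epsilon!r}\n# norm = {rp.norm}\n")
        if emb is not None:
            fh.write(f"# embedding_dimension = {emb.dimension}\n")
            fh.write(f"# embedding_delays = {','.join(map(str, emb.delays))}\n")
        fh.write("i,j\n")
        for a, b in zip(i, j):
            fh.write(f"{a},{b}\n")


def read_rp_coordinates(path: str | Path) -> np.ndarray:
    """Rebuild the binary matrix from a coordinate-list export."""
    n = None
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("# N ="):
                n = int(line.split("=")[1])
                break
    if n is None:
        raise ValueError("missing '# N =' header")
    df = pd.read_csv(path, comment="#")
    R = np.zeros((n, n), dtype=bool)
    R[df["i"].to_numpy(), df["j"].to_numpy()] = True
    return R


# ---------------------------------------------------------------------------
# runners


def _single_traj(cfg: ExperimentConfig, omega: float | None = None) -> Trajectory:
    stim = cfg.stimulus if omega is None else replace(cfg.stimulus, omega=omega)
    return simulate_single(
        cfg.neuron1,
        stim,
        v0=cfg.integration.v0,
        w0=cfg.integration.w0,
        dt=cfg.integration.dt_single,
        t_total=cfg.integration.t_total,
        field_term_over_c=cfg.field_term_over_c,
    )


def run_single_neuron(
    cfg: ExperimentConfig, out_dir: str | Path | None = None
) -> tuple[Trajectory, SpikeTrain, RegimeLabel]:
    """Integrate one forced neuron, detect spikes, classify the regime."""
    traj = _single_traj(cfg)
    t0, t1 = stationary_window(traj.t)
    st = detect_spikes(traj.t, traj.v)
    stat = SpikeTrain(st.times[(st.times >= t0) & (st.times <= t1)], st.threshold, st.refractory)
    omega = float(np.asarray(cfg.stimulus.omega))
    spp = None
    try:
        spp = spikes_per_period(stat, omega, t0, t1)
    except ValueError:
        pass
    if len(stat) >= 3:
        regime = classify_regime(np.diff(stat.times), spp)
    else:
        regime = RegimeLabel("mode_locked" if len(stat) else "quiescent", None, 0)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"omega": omega, "A": cfg.stimulus.A, "VE": cfg.stimulus.VE}
        write_table(trajectory_table(traj), out / "trajectory.csv", meta)
        save_trajectory(traj, out / "trajectory.npz")
        write_table(pd.DataFrame({"spike_time": st.times}), out / "spikes.csv", meta)
        (out / "regime.json").write_text(json.dumps(vars(regime), default=lambda o: None, indent=1))
        (out / "run.json").write_text(json.dumps(_run_record(cfg, None, ["trajectory.csv", "spikes.csv", "regime.json"]), indent=1))
    return traj, st, regime


def run_bifurcation(
    cfg: ExperimentConfig, out_dir: str | Path | None = None
) -> pd.DataFrame:
    """ISI bifurcation table over the config's ω sweep grid."""
    sweep = cfg.sweep if cfg.sweep.variable == "omega" else SweepConfig("omega", 0.01, 0.5, 100)
    df = bifurcation_scan(
        sweep.grid(),
        A=float(np.asarray(cfg.stimulus.A)) or 0.1,
        VE=cfg.stimulus.VE,
        dt=cfg.integration.dt_single,
        t_total=cfg.integration.t_total,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(df, out / "bifurcation.csv", {"A": cfg.stimulus.A})
        (out / "run.json").write_text(json.dumps(_run_record(cfg, None, ["bifurcation.csv"]), indent=1))
    return df


def run_g_sweep(
    cfg: ExperimentConfig,
    out_dir: str | Path | None = None,
    measures: tuple[str, ...] = ("delta_omega", "cpr_p", "cpr_s", "hellinger"),
) -> pd.DataFrame:
    """Coupling sweep: ΔΩ and the recurrence measures per g, plus onsets."""
    grid = cfg.sweep.grid() if cfg.sweep.variable == "g" else np.linspace(0.0, 0.15, 500)
    df = synchronization_scan(
        cfg.coupled(g=grid),
        grid,
        cfg.pipeline(),
        dt=cfg.integration.dt,
        n_steps=cfg.integration.n_steps,
        transient_steps=cfg.integration.transient_steps,
        measures=measures,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"A": cfg.stimulus.A, "omega": cfg.stimulus.omega, "config_hash": config_hash(cfg)}
        write_table(df, out / "g_sweep.csv", meta)
        (out / "run.json").write_text(json.dumps(_run_record(cfg, None, ["g_sweep.csv"]), indent=1))
    return df


def run_amplitude_sweep(
    cfg: ExperimentConfig,
    g_values: tuple[float, ...] = (0.0,),
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Field-amplitude sweep at fixed couplings: (A, g, ΔΩ) rows."""
    sweep = cfg.sweep if cfg.sweep.variable == "A" else SweepConfig("A", 0.0, 0.2, 41)
    amps = sweep.grid()
    frames = []
    for g in g_values:
        coupled = replace(
            cfg.coupled(g=g), stimulus=replace(cfg.stimulus, A=amps)
        )
        traj = simulate_coupled(
            coupled,
            dt=cfg.integration.dt,
            n_steps=cfg.integration.n_steps,
            transient_steps=cfg.integration.transient_steps,
            store_w=False,
        )
        dom = np.asarray(frequency_mismatch(traj.t, traj.v1, traj.v2))
        frames.append(pd.DataFrame({"A": amps, "g": g, "delta_omega": dom}))
    df = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(df, out / "amplitude_sweep.csv", {"omega": cfg.stimulus.omega})
        (out / "run.json").write_text(json.dumps(_run_record(cfg, None, ["amplitude_sweep.csv"]), indent=1))
    return df


def run_surrogate_test(
    cfg: ExperimentConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Block-shuffle surrogate ensemble and the H confidence limit."""
    traj = simulate_coupled(
        cfg.coupled(),
        dt=cfg.integration.dt,
        n_steps=cfg.integration.n_steps,
        transient_steps=cfg.integration.transient_steps,
        store_w=False,
    )
    seed = cfg.sync.seed if seed is None else seed
    hq, hs = surrogate_confidence_limit(
        traj.v1,
        traj.v2,
        traj.dt,
        cfg.pipeline(),
        n_surrogates=cfg.sync.n_surrogates,
        n_blocks=cfg.sync.n_blocks,
        quantile=cfg.sync.quantile,
        rng=seed,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "surrogate_h.txt", hs, fmt=_FLOAT_FMT)
        summary = {"H_quantile": hq, "quantile": cfg.sync.quantile,
                   "n_surrogates": cfg.sync.n_surrogates, "n_blocks": cfg.sync.n_blocks}
        (out / "surrogate_summary.json").write_text(json.dumps(summary, indent=1))
        (out / "run.json").write_text(json.dumps(_run_record(cfg, seed, ["surrogate_h.txt", "surrogate_summary.json"]), indent=1))
    return hq, hs


def export_rp(
    cfg: ExperimentConfig,
    regime: str = "chaos",
    out_dir: str | Path | None = None,
    density: float = 0.15,
) -> RecurrencePlot:
    """Recurrence plot of one single-neuron regime at fixed point density."""
    from .presets import REGIME_OMEGAS

    omega = REGIME_OMEGAS[regime]
    traj = _single_traj(cfg, omega=omega)
    t0, _ = stationary_window(traj.t)
    v = traj.v[traj.t >= t0]
    x, dt_eff, _ = decimate_series(v, traj.dt, cfg.recurrence.max_samples)
    emb = EMBEDDING_PRESETS[regime]
    X = delay_embed(x, emb)
    eps = threshold_for_density(X, density, cfg.recurrence.norm)
    rp = recurrence_matrix(X, eps, cfg.recurrence.norm, density, emb)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        export_rp_coordinates(rp, out / f"rp_{regime}.txt")
        np.savez_compressed(out / f"rp_{regime}.npz", R=rp.R, epsilon=rp.epsilon)
        rr = tau_recurrence_rate_streaming(X, eps, cfg.recurrence.norm, dt_eff)
        write_table(
            pd.DataFrame({"tau_ms": rr.tau_ms, "rr": rr.rr}),
            out / f"rrtau_{regime}.csv",
            {"regime": regime, "density": density, "epsilon": rp.epsilon},
        )
    return rp
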