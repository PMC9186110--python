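"""Euler integration of the firing-rate equations under the trial protocol.

The state is a current per neuron in each of three populations
(excitatory, global inhibitory, local inhibitory). Currents follow

    tau_E dI^E_i/dt = -I^E_i + (1/(N_E <f>)) sum_{j!=i} T_ij V^E_j
                      - (1-c) (1/(N_G P_EG)) sum_j J^{GE}_ij V^G_j
                      - c (1/(N_L f)) sum_j J^{LE}_ij V^L_j + H^ext_i
    tau_I dI^G_i/dt = -I^G_i + (1/(N_E f P_GE)) sum_j J^{EG}_ij V^E_j
    tau_I dI^L_i/dt = -I^L_i + (1/(N_E f)) sum_j J^{EL}_ij V^E_j

(the local-input normalizer is configurable; the default N_E f keeps the
local pathway invariant under network scaling, the alternative N_L f
makes it grow with assembly size)

and rates are instantaneous readouts V^E = phi(I^E) + noise (clipped at
zero), V^G = psi(I^G), V^L = psi(I^L). The readout interpretation is
deliberate: the time constants already sit on the currents, and a second
integration of the rate equations would be unbounded.

A trial starts from the all-zero state, drives every excitatory member of
one chosen pattern with H_ext for the stimulation window, and integrates
to t_end with a fixed Euler step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import h5py
import numpy as np
import yaml

from .memory_graphs import MemoryGraph
from .network_construction import PatternMatrix, WeightSet

__all__ = [
    "SimulationConfig",
    "TransferFunctionSpec",
    "NetworkState",
    "TrialRecord",
    "make_transfer_functions",
    "compute_f_norm",
    "euler_step",
    "run_trial",
    "save_trial",
    "load_trial",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """All tunable parameters of one simulation.

    Times are in milliseconds; rates are proportions of the maximum firing
    rate. ``c`` mixes local (c=1) against global (c=0) inhibition.
    ``f_norm`` is the expected-rate normalization <f> of the excitatory
    recurrence; leave ``None`` to derive it from the memory graph's mean
    degree. ``local_input_norm`` selects the normalizer of the local
    inhibitory input current: ``"printed"`` uses 1/(N_L f), ``"scaled"``
    the size-consistent 1/(N_E f).
    """

    n_e: int = 4000
    n_g: int = 500
    n_l: int = 500
    f: float = 0.01
    c: float = 0.0
    n_li: int = 10
    tau_e: float = 10.0
    tau_i: float = 2.0
    dt: float = 0.1
    t_stim: float = 80.0
    t_end: float = 500.0
    h_ext: float = 0.2
    noise_sd: float = 0.0015
    p_eg: float = 0.5
    p_ge: float = 0.1
    f_norm: float | None = None
    local_input_norm: str = "scaled"
    balance_mode: str = "incoming"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"c must lie in [0,1], got {self.c}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_stim > self.t_end:
            raise ValueError("stimulation window cannot exceed the trial")
        if min(self.n_e, self.n_g, self.n_l) < 1:
            raise ValueError("population sizes must be >= 1")
        if not 0 < self.f < 1:
            raise ValueError("f must lie in (0,1)")
        if self.local_input_norm not in ("printed", "scaled"):
            raise ValueError("local_input_norm must be 'printed' or 'scaled'")
        if self.balance_mode not in ("incoming", "both"):
            raise ValueError("balance_mode must be 'incoming' or 'both'")

    @property
    def n_steps(self) -> int:
        return round(self.t_end / self.dt)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# transfer functions
# ---------------------------------------------------------------------------

def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass(frozen=True)
class TransferFunctionSpec:
    """Input-output curves phi (excitatory) and psi (inhibitory).

    Defaults reconstruct the curves from their published anchors: phi is 0
    at and below ``phi_threshold``, rises smoothly, and saturates at
    ``phi_max`` = 0.08 for inputs above ``phi_sat`` = 0.15; psi rises as
    ``psi_gain * I**psi_exponent`` and continues linearly with the same
    slope for inputs above ``psi_linear_onset`` = 0.6. The sub-saturation
    shapes are a reconstruction (the source shows them only graphically):
    ``phi_shape`` < 1 gives the steep suprathreshold rise an assembly
    needs to ignite its graph neighbors, ``phi_threshold`` keeps weakly
    driven tissue silent so retrieval stays spatially confined, and
    ``psi_gain`` sets where global inhibition balances recurrent
    excitation - calibrated so that the chain protocol with purely global
    inhibition retrieves a compact neighborhood of about five patterns,
    the regime's defining behavior. Tabulated curves (two-column arrays)
    may replace either default.
    """

    phi_max: float = 0.08
    phi_sat: float = 0.15
    phi_threshold: float = 0.01
    phi_shape: float = 0.5
    psi_gain: float = 0.25
    psi_exponent: float = 2.0
    psi_linear_onset: float = 0.6
    phi_table: tuple | None = None
    psi_table: tuple | None = None

    def phi(self, i: np.ndarray) -> np.ndarray:
        if self.phi_table is not None:
            x, y = self.phi_table
            return np.interp(i, x, y)
        span = self.phi_sat - self.phi_threshold
        x = np.clip((np.asarray(i) - self.phi_threshold) / span, 0.0, 1.0)
        return self.phi_max * _smoothstep(x ** self.phi_shape)

    def psi(self, i: np.ndarray) -> np.ndarray:
        if self.psi_table is not None:
            x, y = self.psi_table
            out = np.interp(i, x, y)
            # continue the table's final slope beyond its last point
            slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
            high = np.asarray(i) > x[-1]
            return np.where(high, y[-1] + slope * (np.asarray(i) - x[-1]), out)
        i = np.asarray(i)
        onset = self.psi_linear_onset
        g, eta = self.psi_gain, self.psi_exponent
        power = g * np.clip(i, 0.0, onset) ** eta
        slope = g * eta * onset ** (eta - 1.0)  # continues the curve's slope
        return power + slope * np.clip(i - onset, 0.0, None)


def make_transfer_functions(source: dict | None = None) -> TransferFunctionSpec:
    """Build the transfer-function pair, optionally from tabulated curves.

    ``source`` may carry ``phi`` / ``psi`` entries, each a (n, 2) array of
    (input, rate) anchors; tables must be nondecreasing in both columns.
    """
    if source is None:
        return TransferFunctionSpec()
    kw = {}
    for name in ("phi", "psi"):
        if name in source:
            tab = np.asarray(source[name], dtype=float)
            x, y = tab[:, 0], tab[:, 1]
            if np.any(np.diff(x) <= 0) or np.any(np.diff(y) < -1e-12):
                raise ValueError(f"{name} table must be nondecreasing")
            kw[f"{name}_table"] = (tuple(x), tuple(y))
    params = {k: v for k, v in source.items() if k not in ("phi", "psi")}
    return TransferFunctionSpec(**params, **kw)


def compute_f_norm(graph: MemoryGraph, f: float) -> float:
    """Expected-rate normalization <f> of the excitatory recurrence.

    Uses the mean-degree rule f * (1 + mean_degree / 4), which reproduces
    the chain value f * 1.5 (every vertex of degree 2). For other
    structures this is an extrapolation and can be overridden through
    ``SimulationConfig.f_norm``.
    """
    mean_degree = 2.0 * len(graph.edges) / graph.p
    return f * (1.0 + mean_degree / 4.0)


# ---------------------------------------------------------------------------
# state and integration
# ---------------------------------------------------------------------------

@dataclass
class NetworkState:
    """Currents and rates of all three populations at one time point."""

    i_e: np.ndarray
    i_g: np.ndarray
    i_l: np.ndarray
    v_e: np.ndarray
    v_g: np.ndarray
    v_l: np.ndarray
    t: float = 0.0

    @classmethod
    def zeros(cls, n_e: int, n_g: int, n_l: int) -> "NetworkState":
        return cls(*(np.zeros(n, dtype=np.float32)
                     for n in (n_e, n_g, n_l, n_e, n_g, n_l)))


class DivergenceError(RuntimeError):
    pass


def euler_step(state: NetworkState, weights: WeightSet,
               config: SimulationConfig, tf: TransferFunctionSpec,
               stim_mask: np.ndarray | None, rng: np.random.Generator,
               f_norm: float | None = None) -> NetworkState:
    """Advance all currents by one explicit Euler step, then read out rates.

    ``stim_mask`` flags the excitatory neurons receiving H_ext this step
    (None for no stimulation). Noise is drawn fresh for every excitatory
    neuron; inhibitory readouts are noise-free. Rates are clipped at zero
    after the noise is added.

    States may be batched: arrays of shape (n, k) integrate k independent
    trials of the same network at once (with a per-column ``stim_mask``),
    sharing each weight pass across the batch.
    """
    cfg = config
    fn = f_norm if f_norm is not None else cfg.f_norm
    if fn is None:
        raise ValueError("f_norm not set; pass it or set config.f_norm")
    f32 = np.float32
    drive = weights.exc_recurrent(state.v_e) * f32(1.0 / (cfg.n_e * fn))
    if cfg.c < 1.0:
        drive -= f32((1.0 - cfg.c) / (cfg.n_g * cfg.p_eg)) * weights.global_to_exc(state.v_g)
    if cfg.c > 0.0:
        drive -= f32(cfg.c / (cfg.n_l * cfg.f)) * weights.local_to_exc(state.v_l)
    if stim_mask is not None:
        drive = drive + f32(cfg.h_ext) * stim_mask
    i_e = state.i_e + f32(cfg.dt / cfg.tau_e) * (drive - state.i_e)

    g_in = weights.exc_to_global(state.v_e) * f32(1.0 / (cfg.n_e * cfg.f * cfg.p_ge))
    i_g = state.i_g + f32(cfg.dt / cfg.tau_i) * (g_in - state.i_g)

    l_norm = cfg.n_l * cfg.f if cfg.local_input_norm == "printed" else cfg.n_e * cfg.f
    l_in = weights.exc_to_local(state.v_e) * f32(1.0 / l_norm)
    i_l = state.i_l + f32(cfg.dt / cfg.tau_i) * (l_in - state.i_l)

    if not np.isfinite(i_e).all():
        raise DivergenceError(
            f"excitatory currents diverged at t={state.t + cfg.dt:.1f} ms")

    noise = rng.standard_normal(i_e.shape, dtype=np.float32) * f32(cfg.noise_sd)
    v_e = np.clip(tf.phi(i_e) + noise, f32(0.0), None)
    return NetworkState(i_e=i_e, i_g=i_g, i_l=i_l, v_e=v_e,
                        v_g=tf.psi(i_g), v_l=tf.psi(i_l),
                        t=state.t + cfg.dt)


@dataclass
class TrialRecord:
    """What one stimulation trial leaves behind for analysis.

    ``assembly_traces`` holds the per-pattern summed excitatory rates at
    every step (p x n_steps); ``window_v_e`` the per-neuron rates over the
    recorded window (w x N_E, float32) starting at ``window_t0`` ms;
    ``peak_v_e`` each excitatory neuron's maximum rate over the whole
    trial. Population-mean inhibitory rates are kept per step. Optionally
    the full excitatory rate movie (``full_v_e``) is retained.
    """

    config: SimulationConfig
    stimulated_pattern: int
    seed: int | None
    assembly_traces: np.ndarray
    window_v_e: np.ndarray
    window_t0: float
    peak_v_e: np.ndarray
    mean_v_g: np.ndarray
    mean_v_l: np.ndarray
    f_norm: float
    full_v_e: np.ndarray | None = None
    #: per-neuron rates averaged over requested (t0, t1) windows
    window_means: dict[tuple[float, float], np.ndarray] | None = None

    @property
    def n_steps(self) -> int:
        return self.assembly_traces.shape[1]

    @property
    def p(self) -> int:
        return self.assembly_traces.shape[0]

    def times(self) -> np.ndarray:
        """Time stamps (ms) of recorded steps (state after each update)."""
        dt = self.config.dt
        return dt * (1 + np.arange(self.n_steps))


def run_trial(config: SimulationConfig, weights: WeightSet,
              patterns: PatternMatrix | None = None, stimulated_pattern: int = 0,
              *, graph: MemoryGraph | None = None, seed=None,
              tf: TransferFunctionSpec | None = None,
              record_window: float = 20.0, record_full: bool = False,
              mean_windows: list[tuple[float, float]] | None = None) -> TrialRecord:
    """Integrate one stimulation trial from the all-zero state.

    The stimulated pattern's excitatory members receive H_ext while
    t < t_stim. ``record_window`` sets how many trailing milliseconds of
    per-neuron excitatory rates are kept (the analysis window); assembly
    traces and population-mean inhibitory rates are always kept for every
    step. ``mean_windows`` requests per-neuron rates averaged over extra
    (t0, t1) windows, accumulated streaming (no rate movie is stored).
    Deterministic given (config, seed).
    """
    patterns = patterns if patterns is not None else weights.patterns
    if not 0 <= stimulated_pattern < patterns.p:
        raise ValueError(f"stimulated pattern {stimulated_pattern} out of range")
    tf = tf or make_transfer_functions()
    fn = config.f_norm
    if fn is None:
        if graph is None:
            raise ValueError("need a graph (or config.f_norm) to set <f>")
        fn = compute_f_norm(graph, config.f)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    n_steps = config.n_steps
    w_steps = min(n_steps, round(record_window / config.dt))
    w_start = n_steps - w_steps

    stim = np.zeros(config.n_e, dtype=np.float32)
    stim[patterns.members(stimulated_pattern)] = 1.0
    xi = patterns.xi.astype(np.float32)

    state = NetworkState.zeros(config.n_e, config.n_g, config.n_l)
    traces = np.empty((patterns.p, n_steps))
    window = np.empty((w_steps, config.n_e), dtype=np.float32)
    peaks = np.zeros(config.n_e)
    mean_g = np.empty(n_steps)
    mean_l = np.empty(n_steps)
    full = np.empty((n_steps, config.n_e), dtype=np.float32) if record_full else None
    acc = None
    if mean_windows:
        acc = [(round(t0 / config.dt), round(t1 / config.dt),
                np.zeros(config.n_e)) for t0, t1 in mean_windows]

    for k in range(n_steps):
        mask = stim if state.t < config.t_stim else None
        state = euler_step(state, weights, config, tf, mask, rng, f_norm=fn)
        traces[:, k] = xi @ state.v_e
        np.maximum(peaks, state.v_e, out=peaks)
        mean_g[k] = state.v_g.mean()
        mean_l[k] = state.v_l.mean()
        if k >= w_start:
            window[k - w_start] = state.v_e
        if record_full:
            full[k] = state.v_e
        if acc is not None:
            for k0, k1, total in acc:
                if k0 <= k < k1:
                    total += state.v_e

    return TrialRecord(config=config.with_(f_norm=fn),
                       stimulated_pattern=stimulated_pattern,
                       seed=seed if isinstance(seed, int) else None,
                       assembly_traces=traces, window_v_e=window,
                       window_t0=w_start * config.dt, peak_v_e=peaks,
                       mean_v_g=mean_g, mean_v_l=mean_l, f_norm=fn,
                       full_v_e=full,
                       window_means=(None if acc is None else {
                           w: total / (k1 - k0)
                           for w, (k0, k1, total) in zip(mean_windows, acc)}))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_trial(trial: TrialRecord, path: str | Path, thin: bool = False) -> None:
    """Write a trial record to HDF5; ``thin`` drops the full rate movie."""
    with h5py.File(path, "w") as h5:
        h5.attrs["config"] = json.dumps(trial.config.to_dict())
        h5.attrs["stimulated_pattern"] = trial.stimulated_pattern
        h5.attrs["window_t0"] = trial.window_t0
        h5.attrs["f_norm"] = trial.f_norm
        if trial.seed is not None:
            h5.attrs["seed"] = trial.seed
        h5.create_dataset("assembly_traces", data=trial.assembly_traces)
        h5.create_dataset("window_v_e", data=trial.window_v_e)
        h5.create_dataset("peak_v_e", data=trial.peak_v_e)
        h5.create_dataset("mean_v_g", data=trial.mean_v_g)
        h5.create_dataset("mean_v_l", data=trial.mean_v_l)
        if trial.full_v_e is not None and not thin:
            h5.create_dataset("full_v_e", data=trial.full_v_e)


def load_trial(path: str | Path) -> TrialRecord:
    with h5py.File(path, "r") as h5:
        cfg = SimulationConfig.from_dict(json.loads(h5.attrs["config"]))
        return TrialRecord(
            config=cfg,
            stimulated_pattern=int(h5.attrs["stimulated_pattern"]),
            seed=int(h5.attrs["seed"]) if "seed" in h5.attrs else None,
            assembly_traces=h5["assembly_traces"][...],
            window_v_e=h5["window_v_e"][...],
            window_t0=float(h5.attrs["window_t0"]),
            peak_v_e=h5["peak_v_e"][...],
            mean_v_g=h5["mean_v_g"][...],
            mean_v_l=h5["mean_v_l"][...],
            f_norm=float(h5.attrs["f_norm"]),
            full_v_e=h5["full_v_e"][...] if "full_v_e" in h5 else None,
        )
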