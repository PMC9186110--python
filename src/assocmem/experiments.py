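"""End-to-end experiment drivers: chain sweeps, graph runs, size scaling.

The unit of measurement is a *battery*: one network realization on which
a set of pattern-vertices is stimulated, one trial each, yielding the
cross-trial population-vector correlation matrix and the statistics
derived from it (distance profile and D on the ring; Q and R on arbitrary
graphs). On the ring, a battery may stimulate every pattern or - the
desk-scale default - a distance-covering subset (a "ruler" of marks whose
pairwise ring distances cover every d from 1 to p/2), which estimates the
same profile from far fewer trials.

Each experiment is described by an :class:`ExperimentSpec` and produces
tidy long-format tables plus a JSON run manifest. Per-trial seeds derive
from the base seed through a documented counter scheme -
``SeedSequence([base_seed, *counters])`` - so result files are
byte-reproducible from (spec, base seed) with no hidden global RNG state.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .memory_graphs import MemoryGraph, build_graph, label_propagation
from .network_construction import WeightSet, build_network
from .rate_dynamics import (SimulationConfig, TrialRecord, load_trial,
                            run_trial, save_trial)
from .retrieval_analysis import (assembly_traces, correlation_matrix,
                                 distance_profile, geometric_index_scan,
                                 population_correlation_matrix,
                                 retrieval_range, steady_state_vector)

__all__ = [
    "ExperimentSpec",
    "trial_seed",
    "ruler_marks",
    "simulate_trial",
    "chain_battery",
    "graph_battery",
    "run_chain_experiment",
    "run_graph_experiment",
    "run_scaling_experiment",
    "analyze_battery",
]

log = logging.getLogger("assocmem")

_CSV_KW = dict(index=False, float_format="%.10g")


@dataclass
class ExperimentSpec:
    """Declarative description of one experiment."""

    graph: str | dict = "ring"
    config: SimulationConfig = field(default_factory=SimulationConfig)
    c_values: tuple[float, ...] = (0.0,)
    batteries: int = 5                      # repetitions per c value
    stimulated: tuple[int, ...] | str = "ruler"  # vertex set, "ruler", or "all"
    base_seed: int = 0
    size_multipliers: tuple[int, ...] = (1,)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for c in self.c_values:
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"c={c} outside [0,1]")
        if self.batteries < 1:
            raise ValueError("batteries must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentSpec":
        data = dict(data)
        if isinstance(data.get("config"), dict):
            data["config"] = SimulationConfig.from_dict(data["config"])
        for key in ("c_values", "stimulated", "size_multipliers"):
            if isinstance(data.get(key), list):
                data[key] = tuple(data[key])
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown experiment keys: {sorted(unknown)}")
        return cls(**data)


def trial_seed(base_seed: int, *counters: int) -> int:
    """Deterministic seed below 2^31 from the base seed and counters."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, counters)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def ruler_marks(p: int) -> tuple[int, ...]:
    """A stimulation set whose pairwise ring distances cover 1..p/2.

    Contiguous marks 0..5 plus spokes every 5 vertices out to p/2: the
    spoke-minus-base differences tile 5..p/2 with no gaps, so the distance
    profile is estimable at every d from ~p/8 trials instead of p.
    """
    if p <= 20:
        return tuple(range(p))
    half = p // 2
    marks = set(range(10)) | set(range(15, half + 1, 5)) | {half}
    return tuple(sorted(marks))


def _config_hash(config: SimulationConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _default_stim_vertex(graph: MemoryGraph) -> int:
    """Documented default stimulation sites for the builtin structures."""
    meta = graph.metadata
    if "central_vertex" in meta:          # Tutte: the vertex joining the rooms
        return int(meta["central_vertex"])
    if "near_doorway_vertex" in meta:     # multiroom: wall cell beside a door
        return int(meta["near_doorway_vertex"])
    if graph.name == "karate":
        return 0                          # the instructor hub
    if graph.name == "k5-3-chain":
        return 2                          # a core vertex of the first fragment
    return 0


def _network_for(graph: MemoryGraph, config: SimulationConfig,
                 seed: int) -> WeightSet:
    return build_network(graph, n_e=config.n_e, n_g=config.n_g, n_l=config.n_l,
                         f=config.f, n_li=config.n_li, p_eg=config.p_eg,
                         p_ge=config.p_ge, seed=seed,
                         balance_mode=config.balance_mode)


def simulate_trial(graph: MemoryGraph, config: SimulationConfig,
                   stimulated: int, seed: int, **trial_kw) -> TrialRecord:
    """Build a fresh network realization and run one trial on it."""
    weights = _network_for(graph, config, seed)
    return run_trial(config.with_(seed=seed), weights,
                     stimulated_pattern=stimulated, graph=graph,
                     seed=trial_seed(seed, stimulated), **trial_kw)


# ---------------------------------------------------------------------------
# batteries
# ---------------------------------------------------------------------------

def _run_battery(graph: MemoryGraph, config: SimulationConfig, seed: int,
                 stim_set, out_dir: Path | None = None):
    """One network realization, one trial per stimulated vertex.

    Returns (states, peaks) where states maps vertex -> steady-state
    population vector and peaks is the across-trial maximum per-neuron
    rate (for the selective-neurons variant). By default the battery's
    trials are integrated batched (one state column per trial), sharing
    every weight pass; with ``out_dir`` set, trials run one by one so
    full per-trial records can be persisted.
    """
    weights = _network_for(graph, config, seed)
    config = config.with_(seed=seed)  # records carry the network seed
    states: dict[int, np.ndarray] = {}
    peaks = np.zeros(config.n_e)
    if out_dir is None:
        return _run_battery_batched(graph, config, weights, seed, stim_set)
    for stim in stim_set:
        trial = run_trial(config, weights, stimulated_pattern=int(stim),
                          graph=graph, seed=trial_seed(seed, int(stim)))
        states[int(stim)] = steady_state_vector(trial)
        np.maximum(peaks, trial.peak_v_e, out=peaks)
        save_trial(trial, out_dir / f"trial_s{seed}_v{stim}.h5")
    return states, peaks


def _run_battery_batched(graph: MemoryGraph, config: SimulationConfig,
                         weights: WeightSet, seed: int, stim_set,
                         window: float = 20.0):
    """Integrate a whole battery as one batched system.

    All trials share the network; each state array carries one column per
    stimulated vertex. The steady-state vectors are the column means over
    the trailing ``window`` ms. Deterministic given (config, seed); the
    battery noise stream derives from SeedSequence([seed, 7919]).
    """
    from .rate_dynamics import (NetworkState, compute_f_norm, euler_step,
                                make_transfer_functions)
    stims = [int(s) for s in stim_set]
    k = len(stims)
    fn = config.f_norm if config.f_norm is not None \
        else compute_f_norm(graph, config.f)
    tf = make_transfer_functions()
    rng = np.random.default_rng(trial_seed(seed, 7919))
    stim_mask = np.zeros((config.n_e, k), dtype=np.float32)
    for col, s in enumerate(stims):
        stim_mask[weights.patterns.members(s), col] = 1.0
    state = NetworkState(*(np.zeros((n, k), dtype=np.float32) for n in
                           (config.n_e, config.n_g, config.n_l) * 2))
    n_steps = config.n_steps
    w_steps = min(n_steps, round(window / config.dt))
    w_start = n_steps - w_steps
    ss_sum = np.zeros((config.n_e, k))
    peaks = np.zeros((config.n_e, k), dtype=np.float32)
    for step in range(n_steps):
        mask = stim_mask if state.t < config.t_stim else None
        state = euler_step(state, weights, config, tf, mask, rng, f_norm=fn)
        np.maximum(peaks, state.v_e, out=peaks)
        if step >= w_start:
            ss_sum += state.v_e
    ss = ss_sum / w_steps
    states = {s: ss[:, col].copy() for col, s in enumerate(stims)}
    return states, peaks.max(axis=1).astype(np.float64)


def chain_battery(graph: MemoryGraph, config: SimulationConfig, seed: int,
                  stim_set=None, epsilon: float = 0.05, y: int = 5):
    """Ring battery: distance profile and range of retrieval D.

    Returns (D, profile, correlation matrix).
    """
    stim_set = ruler_marks(graph.p) if stim_set is None else stim_set
    states, _ = _run_battery(graph, config, seed, stim_set)
    corr = population_correlation_matrix(states, graph.p)
    prof = distance_profile(corr, graph)
    rr = retrieval_range(prof, epsilon=epsilon, y=y)
    return rr.d, prof, corr


def graph_battery(graph: MemoryGraph, config: SimulationConfig, seed: int,
                  stim_set=None) -> dict:
    """Arbitrary-graph battery: Q and R(d) for every d, on all neurons and
    on the selective subset (neurons above 0.02 in any trial)."""
    stim_set = range(graph.p) if stim_set is None else stim_set
    states, peaks = _run_battery(graph, config, seed, stim_set)
    labels = label_propagation(graph, seed=seed)
    out = dict(seed=seed, n_trials=len(states))
    sel = peaks >= 0.02
    for variant, mask in (("all", None), ("sel", sel)):
        corr = population_correlation_matrix(states, graph.p, mask=mask)
        res = geometric_index_scan(corr, graph, labels=labels)
        best_d, best_r = res.best
        out[f"Q_{variant}"] = res.q
        out[f"best_d_{variant}"] = best_d
        out[f"best_R_{variant}"] = best_r
        for d, r in res.r_by_d.items():
            out[f"R_{variant}_d{d}"] = r
    return out


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def _stim_set_for(spec: ExperimentSpec, graph: MemoryGraph):
    if spec.stimulated == "ruler":
        return ruler_marks(graph.p)
    if spec.stimulated == "all":
        return tuple(range(graph.p))
    return tuple(int(v) for v in spec.stimulated)


def run_chain_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Sweep c on the ring chain: per (c, battery), a fresh network and a
    battery of stimulations giving one distance profile and one D.

    Returns a long table (c, battery, seed, D); profiles are written
    alongside when ``spec.out_dir`` is set.
    """
    graph = build_graph(spec.graph)
    stim_set = _stim_set_for(spec, graph)
    rows, profiles = [], []
    for ci, c in enumerate(spec.c_values):
        config = spec.config.with_(c=c)
        for bi in range(spec.batteries):
            seed = trial_seed(spec.base_seed, ci, bi)
            t0 = time.perf_counter()
            d, prof, _ = chain_battery(graph, config, seed, stim_set)
            log.info("chain c=%.3f battery=%d seed=%d D=%d (%.1fs)",
                     c, bi, seed, d, time.perf_counter() - t0)
            rows.append(dict(c=c, battery=bi, seed=seed, D=d))
            profiles.append(dict(c=c, battery=bi, **{
                f"d{dd}": prof.c_d[dd] for dd in range(prof.c_d.size)}))
    result = pd.DataFrame(rows)
    if spec.out_dir:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_csv(out / "chain_sweep.csv", **_CSV_KW)
        pd.DataFrame(profiles).to_csv(out / "chain_profiles.csv", **_CSV_KW)
        _write_manifest(out, spec)
    return result


def run_graph_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Per (c, battery): stimulate every vertex (or the given subset) of
    the graph and tabulate Q, R(d) for d up to the diameter, and the best
    (d, R), for all neurons and for the selective subset."""
    graph = build_graph(spec.graph)
    if spec.stimulated in ("ruler", "all"):
        stim_set = tuple(range(graph.p))
    else:
        stim_set = tuple(int(v) for v in spec.stimulated)
        for v in stim_set:
            if not 0 <= v < graph.p:
                raise ValueError(f"stimulated vertex {v} not in graph")
    rows = []
    for ci, c in enumerate(spec.c_values):
        config = spec.config.with_(c=c)
        for bi in range(spec.batteries):
            seed = trial_seed(spec.base_seed, ci, bi)
            t0 = time.perf_counter()
            row = graph_battery(graph, config, seed, stim_set)
            log.info("graph %s c=%.3f battery=%d seed=%d Q_all=%.3f (%.1fs)",
                     graph.name, c, bi, seed, row["Q_all"],
                     time.perf_counter() - t0)
            rows.append(dict(c=c, battery=bi, **row))
    result = pd.DataFrame(rows)
    if spec.out_dir:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_csv(out / "graph_runs.csv", **_CSV_KW)
        _write_manifest(out, spec)
    return result


def run_scaling_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Chain protocol at fixed c across scaled population sizes.

    The multiplier m scales N_E directly; the inhibitory pools scale as
    the cube root of m (so the published enlarged condition 8x excitatory
    with 2x inhibitory, N_E=32,000 and N_G=N_L=1,000, sits on the ladder).
    Reports per-size D and the across-battery variance of the profile as
    the finite-size noise measure.
    """
    base = spec.config
    graph = build_graph(spec.graph)
    stim_set = _stim_set_for(spec, graph)
    rows = []
    for mi, m in enumerate(spec.size_multipliers):
        if m < 1:
            raise ValueError("size multipliers must be >= 1")
        inh_m = max(1, round(m ** (1.0 / 3.0)))
        config = base.with_(n_e=base.n_e * m, n_g=base.n_g * inh_m,
                            n_l=base.n_l * inh_m)
        profs = []
        for bi in range(spec.batteries):
            seed = trial_seed(spec.base_seed, mi, bi)
            d, prof, _ = chain_battery(graph, config, seed, stim_set)
            profs.append(prof.c_d)
            rows.append(dict(multiplier=m, n_e=config.n_e, n_g=config.n_g,
                             n_l=config.n_l, battery=bi, seed=seed, D=d,
                             profile_var=np.nan))
        var = (float(np.var(np.stack(profs), axis=0).mean())
               if len(profs) > 1 else np.nan)
        for r in rows[-spec.batteries:]:
            r["profile_var"] = var
    result = pd.DataFrame(rows)
    if spec.out_dir:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_csv(out / "scaling.csv", **_CSV_KW)
        _write_manifest(out, spec)
    return result


# ---------------------------------------------------------------------------
# re-analysis of stored records
# ---------------------------------------------------------------------------

def analyze_battery(paths: list, graph: MemoryGraph,
                    labels_seed: int = 0) -> dict:
    """Recompute battery statistics from stored trial records.

    Produces exactly what the inline drivers compute: the population-
    vector correlation matrix, the distance profile and D when the graph
    is a ring, and Q / R(d) otherwise (or both, on a ring).
    """
    states, peaks = {}, None
    for path in paths:
        trial = load_trial(path)
        states[trial.stimulated_pattern] = steady_state_vector(trial)
        peaks = (trial.peak_v_e if peaks is None
                 else np.maximum(peaks, trial.peak_v_e))
    corr = population_correlation_matrix(states, graph.p)
    out: dict = {"n_trials": len(states)}
    if np.all(graph.degrees() == 2):
        prof = distance_profile(corr, graph)
        out["profile"] = prof.c_d
        out["D"] = retrieval_range(prof).d
    if not np.isnan(corr.c).any():
        labels = label_propagation(graph, seed=labels_seed)
        res = geometric_index_scan(corr, graph, labels=labels)
        out["Q"] = res.q
        out["R_by_d"] = res.r_by_d
        out["best_d"], out["best_R"] = res.best
    return out


def analyze_trial(trial: TrialRecord, patterns) -> dict:
    """Within-trial (temporal) statistics of a single stored record."""
    traces = assembly_traces(trial, patterns)
    corr = correlation_matrix(traces)
    return {"temporal_correlations": corr.c,
            "zero_variance": corr.zero_variance,
            "mean_offdiag": corr.mean_offdiag()}


def _write_manifest(out: Path, spec: ExperimentSpec) -> None:
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(spec.config),
        "base_seed": spec.base_seed,
        "graph": spec.graph if isinstance(spec.graph, str) else dict(spec.graph),
        "c_values": list(spec.c_values),
        "batteries": spec.batteries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
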