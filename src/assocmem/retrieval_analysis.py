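"""Trial statistics: assembly correlations, retrieval range, Q and R indices.

Correlations between memory patterns come in two modes:

* **population-vector (battery) mode** - the default for the experiment
  drivers. Each pattern is stimulated in its own trial on the same
  network realization; each trial's excitatory steady state is
  time-averaged over the final analysis window (WS = 20 ms) into one
  population vector, and C_{mu,nu} is the Pearson correlation across
  neurons between the vectors of the trials that stimulated mu and nu.
  Retrieval states of nearby patterns overlap, so C decays with graph
  distance; trials that converge to the same global state correlate at
  ~1, complementary states at negative values.

* **within-trial temporal mode** - from a single trial, each pattern's
  summed-rate trace over the window is correlated against the others
  over time. With independent per-step noise on every neuron, temporal
  trace fluctuations are noise-dominated, so this mode is kept for
  time-course inspection rather than for the distance statistics.

On a ring the correlation-versus-distance profile yields the range of
retrieval D through a plateau-detection rule; on arbitrary graphs the
correlation matrix is compared against label-propagation communities
(clustering index Q) and against closed d-neighborhoods (geometric
index R).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .memory_graphs import CommunityLabels, MemoryGraph, shortest_path_matrix
from .network_construction import PatternMatrix
from .rate_dynamics import TrialRecord

__all__ = [
    "AssemblyTraces",
    "CorrelationMatrix",
    "DistanceProfile",
    "RetrievalRange",
    "IndexResult",
    "selective_mask",
    "assembly_traces",
    "steady_state_vector",
    "correlation_matrix",
    "population_correlation_matrix",
    "distance_profile",
    "mean_profile",
    "retrieval_range",
    "clustering_index",
    "geometric_index",
    "geometric_index_scan",
]


@dataclass
class AssemblyTraces:
    """Summed excitatory rates per pattern over an analysis window.

    ``a[mu, t]`` is the sum of V^E over pattern mu's members (optionally
    restricted to a neuron mask) at window step t.
    """

    a: np.ndarray
    window: tuple[float, float]
    mask_applied: bool = False

    @property
    def p(self) -> int:
        return self.a.shape[0]

    @property
    def w(self) -> int:
        return self.a.shape[1]


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations between assembly traces.

    Zero-variance (silent) assemblies are flagged; their off-diagonal
    correlations are defined as 0 so downstream indices stay computable.
    """

    c: np.ndarray
    zero_variance: np.ndarray

    @property
    def p(self) -> int:
        return self.c.shape[0]

    def mean_offdiag(self) -> float:
        c = self.c.copy()
        np.fill_diagonal(c, np.nan)
        return float(np.nanmean(c))


@dataclass
class DistanceProfile:
    """Mean correlation C_d at each ring distance d = 0..p//2."""

    c_d: np.ndarray
    p: int
    per_trial: bool = True

    @property
    def d_max(self) -> int:
        return self.c_d.size - 1


@dataclass
class RetrievalRange:
    """Range of retrieval D with the plateau-detection parameters used."""

    d: int
    epsilon: float
    y: int
    p: int


@dataclass
class IndexResult:
    """Clustering index Q and geometric index R(d) for one trial."""

    q: float
    r_by_d: dict[int, float]
    labels_seed: int | None = None

    @property
    def best(self) -> tuple[int, float]:
        """(d, R) of the largest geometric index; smallest d on ties."""
        best_d = max(sorted(self.r_by_d), key=lambda d: self.r_by_d[d])
        return best_d, self.r_by_d[best_d]


# ---------------------------------------------------------------------------
# traces and correlations
# ---------------------------------------------------------------------------

def selective_mask(trial: TrialRecord, threshold: float = 0.02) -> np.ndarray:
    """Neurons whose rate reached ``threshold`` (proportion of maximum) at
    any point of the trial."""
    return trial.peak_v_e >= threshold


def assembly_traces(trial: TrialRecord, patterns: PatternMatrix,
                    window: tuple[float, float] | None = None,
                    mask: np.ndarray | None = None) -> AssemblyTraces:
    """Per-pattern summed rates over ``window`` (ms), default the trial's
    recorded steady-state window; ``mask`` restricts to a neuron subset."""
    cfg = trial.config
    t0_rec = trial.window_t0
    if window is None:
        window = (t0_rec, cfg.t_end)
    t0, t1 = window
    if mask is None and (t0, t1) == (0.0, cfg.t_end) and trial.full_v_e is None:
        # whole-trial, all neurons: the running assembly traces already hold it
        return AssemblyTraces(a=trial.assembly_traces.copy(), window=window)
    if t0 >= t0_rec - 1e-9 and t1 <= cfg.t_end + 1e-9:
        v = trial.window_v_e
        offset = t0_rec
    elif trial.full_v_e is not None:
        v = trial.full_v_e
        offset = 0.0
    else:
        raise ValueError(
            f"window {window} outside recorded rates [{t0_rec}, {cfg.t_end}] ms")
    k0 = round((t0 - offset) / cfg.dt)
    k1 = round((t1 - offset) / cfg.dt)
    v = np.asarray(v[k0:k1], dtype=np.float64)
    xi = patterns.xi
    if mask is not None:
        cols = np.flatnonzero(mask)
        xi = xi[:, cols]
        v = v[:, cols]
    return AssemblyTraces(a=xi @ v.T, window=(t0, t1), mask_applied=mask is not None)


def steady_state_vector(trial: TrialRecord,
                        window: tuple[float, float] | None = None) -> np.ndarray:
    """Per-neuron excitatory rates time-averaged over the analysis window
    (default: the trial's recorded trailing window)."""
    cfg = trial.config
    if window is None:
        return np.asarray(trial.window_v_e, dtype=np.float64).mean(axis=0)
    t0, t1 = window
    if t0 >= trial.window_t0 - 1e-9 and t1 <= cfg.t_end + 1e-9:
        v, offset = trial.window_v_e, trial.window_t0
    elif trial.full_v_e is not None:
        v, offset = trial.full_v_e, 0.0
    else:
        raise ValueError(f"window {window} outside recorded rates")
    k0, k1 = round((t0 - offset) / cfg.dt), round((t1 - offset) / cfg.dt)
    return np.asarray(v[k0:k1], dtype=np.float64).mean(axis=0)


def population_correlation_matrix(states: dict[int, np.ndarray], p: int,
                                  mask: np.ndarray | None = None) -> CorrelationMatrix:
    """Cross-trial correlation matrix from steady-state population vectors.

    ``states`` maps stimulated pattern id -> steady-state vector. Entries
    for pattern pairs without trials are NaN; the distance profile and the
    Q/R indices average over the available entries. ``mask`` restricts the
    correlation to a neuron subset (the selective-neurons variant).
    """
    c = np.full((p, p), np.nan)
    zero = np.zeros(p, dtype=bool)
    ids = sorted(states)
    vecs = {}
    for mu in ids:
        v = np.asarray(states[mu], dtype=np.float64)
        if mask is not None:
            v = v[mask]
        sd = v.std()
        zero[mu] = sd == 0.0
        vecs[mu] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    n = len(next(iter(vecs.values()))) if vecs else 0
    for a, mu in enumerate(ids):
        c[mu, mu] = 1.0
        for nu in ids[a + 1:]:
            val = 0.0 if (zero[mu] or zero[nu]) else float(
                vecs[mu] @ vecs[nu] / n)
            c[mu, nu] = c[nu, mu] = min(1.0, max(-1.0, val))
    return CorrelationMatrix(c=c, zero_variance=zero)


def correlation_matrix(traces: AssemblyTraces) -> CorrelationMatrix:
    """Pearson correlation over time between every pair of assembly traces."""
    a = traces.a
    if traces.w < 2:
        raise ValueError("need at least two window steps to correlate")
    centered = a - a.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered ** 2).mean(axis=1))
    zero = sd == 0.0
    safe = np.where(zero, 1.0, sd)
    cov = (centered @ centered.T) / a.shape[1]
    c = cov / np.outer(safe, safe)
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    return CorrelationMatrix(c=c, zero_variance=zero)


# ---------------------------------------------------------------------------
# ring distance profile and range of retrieval
# ---------------------------------------------------------------------------

def _require_ring(graph: MemoryGraph) -> None:
    if not np.all(graph.degrees() == 2):
        raise ValueError(
            "distance profile is defined on the ring chain; "
            "use clustering_index / geometric_index for other structures")


def distance_profile(c: CorrelationMatrix, graph: MemoryGraph,
                     stimulated: int | None = None) -> DistanceProfile:
    """Correlation against ring distance, C_d for d = 0..p//2.

    With ``stimulated`` given (the per-trial form), C_d averages the
    stimulated pattern's correlation with its two patterns at distance d;
    otherwise all rows contribute, mu running over every pattern.
    """
    _require_ring(graph)
    p = graph.p
    if c.p != p:
        raise ValueError("correlation matrix and graph disagree on p")
    d_max = p // 2
    rows = [stimulated] if stimulated is not None else list(range(p))
    prof = np.empty(d_max + 1)
    for d in range(d_max + 1):
        vals = np.array([c.c[mu, (mu + d) % p] for mu in rows] +
                        [c.c[mu, (mu - d) % p] for mu in rows])
        if np.all(np.isnan(vals)):
            raise ValueError(f"no correlation available at distance d={d}; "
                             "the trial battery must cover every distance")
        prof[d] = float(np.nanmean(vals))
    return DistanceProfile(c_d=prof, p=p, per_trial=stimulated is not None)


def mean_profile(profiles: list[DistanceProfile]) -> DistanceProfile:
    """Average per-trial profiles (the black line over the gray lines)."""
    c_d = np.mean([pr.c_d for pr in profiles], axis=0)
    return DistanceProfile(c_d=c_d, p=profiles[0].p, per_trial=False)


def retrieval_range(profile: DistanceProfile, epsilon: float = 0.05,
                    y: int = 5) -> RetrievalRange:
    """Range of retrieval D by plateau detection on the distance profile.

    Successive differences |C_{d-1} - C_d| are scanned outward from the
    onset of decay (the first d >= 2 with a difference >= epsilon): D is
    the first d from which Y consecutive differences all stay below
    epsilon. A profile that never moves by epsilon gives the minimal D=2;
    if no plateau of length Y follows the decay, D = p/2.
    """
    p = profile.p
    d_max = p // 2
    if profile.d_max < d_max:
        raise ValueError(f"profile must reach d = p/2 = {d_max}")
    diffs = np.abs(np.diff(profile.c_d))  # diffs[d-1] = |C_{d-1} - C_d|
    big = np.flatnonzero(diffs[1:] >= epsilon) + 2  # d values with large diff
    if big.size == 0:
        return RetrievalRange(d=2, epsilon=epsilon, y=y, p=p)
    onset = int(big[0])
    for d in range(onset, d_max - y + 2):
        if np.all(diffs[d - 1:d - 1 + y] < epsilon):
            return RetrievalRange(d=d, epsilon=epsilon, y=y, p=p)
    return RetrievalRange(d=d_max, epsilon=epsilon, y=y, p=p)


# ---------------------------------------------------------------------------
# graph-structure indices
# ---------------------------------------------------------------------------

def clustering_index(c: CorrelationMatrix, labels: CommunityLabels) -> float:
    """Q: mean signed agreement between correlations and community
    co-membership, (1/(p^2-p)) sum_{mu != nu} LPA(mu,nu) C_{mu,nu}."""
    if labels.labels.size != c.p:
        raise ValueError("labels must cover all patterns")
    return _signed_offdiag_mean(labels.agreement_sign(), c.c)


def _signed_offdiag_mean(sign: np.ndarray, c: np.ndarray) -> float:
    """Mean of sign * C over off-diagonal entries (available ones, when
    the matrix is partial)."""
    prod = sign * c
    np.fill_diagonal(prod, np.nan)
    return float(np.nanmean(prod))


def geometric_index(c: CorrelationMatrix, graph: MemoryGraph, d: int,
                    dist: np.ndarray | None = None) -> float:
    """R(d): mean signed agreement between correlations and closed
    d-neighborhood co-membership."""
    if dist is None:
        dist = shortest_path_matrix(graph)
    if not 1 <= d <= dist.max():
        raise ValueError(f"d={d} outside 1..diameter={dist.max()}")
    la = np.where(dist <= d, 1.0, -1.0)  # LA(mu | v, d), symmetric
    return _signed_offdiag_mean(la, c.c)


def geometric_index_scan(c: CorrelationMatrix, graph: MemoryGraph,
                         labels: CommunityLabels | None = None) -> IndexResult:
    """Q plus R(d) for every d from 1 to the diameter."""
    dist = shortest_path_matrix(graph)
    r_by_d = {d: geometric_index(c, graph, d, dist=dist)
              for d in range(1, int(dist.max()) + 1)}
    q = clustering_index(c, labels) if labels is not None else float("nan")
    return IndexResult(q=q, r_by_d=r_by_d,
                       labels_seed=labels.seed if labels is not None else None)
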