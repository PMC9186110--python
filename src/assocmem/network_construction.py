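"""Pattern generation, graph embedding, connectivity sampling, balancing.

Memory patterns are sparse random binary vectors over the excitatory
population. The extended association rule couples neurons that share a
pattern or sit in graph-adjacent patterns:

    T_ij = sum_mu xi_i^mu xi_j^mu  +  sum_mu sum_{k in K(mu)} xi_i^mu xi_j^k

i.e. T = xi^T (I + A) xi with A the adjacency matrix of the memory
structure. Inhibitory wiring comes in two flavors: one global pool with
Bernoulli connectivity to/from all excitatory neurons, and per-pattern
local pools fully connected to their pattern's excitatory assembly.
Cross-population weights are balanced per excitatory neuron so that
neurons receiving stronger recurrent excitation also receive (and drive)
proportionally stronger inhibition, with the balancing factors averaging
exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import scipy.sparse as sp

from numba import njit

from .memory_graphs import MemoryGraph


@njit(fastmath=True, cache=True)
def _u8_matvec(mask: np.ndarray, v: np.ndarray, out: np.ndarray) -> None:
    """out = mask @ v for a dense 0/1 uint8 mask (memory-bound hot loop)."""
    n, m = mask.shape
    for i in range(n):
        acc = np.float32(0.0)
        row = mask[i]
        for j in range(m):
            acc += row[j] * v[j]
        out[i] = acc



__all__ = [
    "PatternMatrix",
    "ConnectivityMasks",
    "WeightSet",
    "sample_patterns",
    "assign_local_inhibitory",
    "generate_patterns",
    "build_association_weights",
    "sample_connectivity",
    "balance_weights",
    "build_network",
    "save_patterns",
    "load_patterns",
]

#: materialize T densely up to this many excitatory neurons
_DENSE_T_LIMIT = 8000


@dataclass
class PatternMatrix:
    """Binary pattern membership plus per-pattern local-inhibitory pools.

    ``xi`` is a p x N_E CSR matrix with i.i.d. Bernoulli(f) entries;
    ``li_members`` holds, for each pattern, the ids (into 0..N_L-1) of the
    local inhibitory neurons in its joint assembly.
    """

    xi: sp.csr_matrix
    li_members: list[np.ndarray]
    f: float
    seed: int | None = None

    @property
    def p(self) -> int:
        return self.xi.shape[0]

    @property
    def n_e(self) -> int:
        return self.xi.shape[1]

    def members(self, mu: int) -> np.ndarray:
        """Excitatory neuron ids belonging to pattern mu."""
        return self.xi.indices[self.xi.indptr[mu]:self.xi.indptr[mu + 1]]

    def li_indicator(self, n_l: int) -> sp.csr_matrix:
        """p x N_L binary indicator of local-inhibitory membership."""
        indptr = np.cumsum([0] + [len(m) for m in self.li_members])
        indices = np.concatenate(self.li_members) if self.li_members else np.array([], int)
        data = np.ones(indices.size)
        return sp.csr_matrix((data, indices, indptr), shape=(self.p, n_l))


@dataclass
class ConnectivityMasks:
    """Bernoulli masks between the excitatory and global inhibitory pools.

    ``ge_mask`` (N_E x N_G, dense uint8) marks global->excitatory
    connections, sampled at probability ``p_eg``; ``eg_mask`` (N_G x N_E,
    CSR) marks excitatory->global connections at probability ``p_ge``.
    The probability names follow the source convention in which each one
    appears in (and cancels from) the current normalizer of the opposite
    population: P_EG divides the global-inhibition term of the excitatory
    current, P_GE the excitatory drive of the global pool.
    """

    ge_mask: np.ndarray
    eg_mask: sp.csr_matrix
    p_eg: float
    p_ge: float
    seed: int | None = None


@dataclass
class WeightSet:
    """All connection weights, kept in factorized form.

    The excitatory recurrence T = xi^T (I + A) xi is never materialized for
    the integrator; :meth:`exc_recurrent` applies it (minus the diagonal,
    which the current equation excludes) through the factors, which is
    algebraically identical. ``scale`` holds the per-excitatory-neuron
    balancing factor with mean exactly 1; every inhibitory<->excitatory
    weight incident on excitatory neuron i equals ``scale[i]`` wherever the
    corresponding mask or joint-assembly membership permits a connection.
    """

    patterns: PatternMatrix
    masks: ConnectivityMasks
    assoc: sp.csr_matrix            # I + A, p x p
    scale: np.ndarray               # balancing factor per excitatory neuron
    t_diag: np.ndarray              # diagonal of T
    le_mask: sp.csr_matrix          # N_E x N_L joint-assembly membership
    #: "incoming" scales only inhibitory->excitatory weights by the target
    #: neuron's factor (the default: inhibition received is proportional to
    #: recurrent excitation received); "both" additionally scales
    #: excitatory->inhibitory weights by the source neuron's factor
    balance_mode: str = "incoming"
    _T: object = field(default=None, repr=False)

    # -- weight matrices on demand --------------------------------------
    @property
    def T(self):
        """Association weights (dense for small networks, CSR above
        8000 excitatory neurons)."""
        if self._T is None:
            xi = self.patterns.xi.astype(np.float64)
            t = (xi.T @ (self.assoc @ xi)).tocsr()
            if self.patterns.n_e <= _DENSE_T_LIMIT:
                t = t.toarray()
            self._T = t
        return self._T

    # -- raw synaptic sums used by the rate equations --------------------
    # The integrator runs in float32 (the matvecs are memory-bound); the
    # cached operators below hold float32 / uint8 copies of the weights.

    def _ops(self) -> dict:
        cache = getattr(self, "_ops_cache", None)
        if cache is None:
            scale32 = self.scale.astype(np.float32)
            src32 = (scale32 if self.balance_mode == "both"
                     else np.ones_like(scale32))
            eg = self.masks.eg_mask.tocsr().astype(np.float32)
            eg_scaled = eg.multiply(src32[None, :]).tocsr()
            le32 = self.le_mask.astype(np.float32)
            el_scaled = le32.multiply(src32[:, None]).T.tocsr()
            cache = {
                "xi": self.patterns.xi.astype(np.float32),
                "assoc": (self.assoc.astype(np.float32)
                          if self.assoc is not None else None),
                "t_diag": self.t_diag.astype(np.float32),
                "scale": scale32,
                "ge_u8": np.ascontiguousarray(self.masks.ge_mask, dtype=np.uint8),
                "ge_f32": np.ascontiguousarray(self.masks.ge_mask,
                                               dtype=np.float32),
                "ge_out": np.empty(self.scale.size, dtype=np.float32),
                "eg_scaled": eg_scaled,
                "le": le32,
                "el_scaled": el_scaled,
                "T32": (None if self.assoc is not None
                        else sp.csr_matrix(self.T, dtype=np.float32)),
            }
            self._ops_cache = cache
        return cache

    # Every operator accepts rate vectors (n,) or batched matrices (n, k)
    # whose columns are independent trials on this same network.

    def exc_recurrent(self, v_e: np.ndarray) -> np.ndarray:
        """sum_{j != i} T_ij V_j for every excitatory neuron i."""
        ops = self._ops()
        v = np.asarray(v_e, dtype=np.float32)
        diag = ops["t_diag"] if v.ndim == 1 else ops["t_diag"][:, None]
        if ops["assoc"] is None:  # built from an explicit T without the graph
            return np.asarray(ops["T32"] @ v).reshape(v.shape) - diag * v
        return ops["xi"].T @ (ops["assoc"] @ (ops["xi"] @ v)) - diag * v

    def global_to_exc(self, v_g: np.ndarray) -> np.ndarray:
        """sum_j J^{GE}_ij V^G_j (weight scale_i on masked connections)."""
        ops = self._ops()
        v = np.asarray(v_g, dtype=np.float32)
        if v.ndim == 1:
            _u8_matvec(ops["ge_u8"], v, ops["ge_out"])
            return ops["scale"] * ops["ge_out"]
        out = np.empty((ops["ge_u8"].shape[0], v.shape[1]), dtype=np.float32)
        np.matmul(ops["ge_f32"], np.ascontiguousarray(v), out=out)
        return ops["scale"][:, None] * out

    def local_to_exc(self, v_l: np.ndarray) -> np.ndarray:
        """sum_j J^{LE}_ij V^L_j over joint-assembly connections."""
        ops = self._ops()
        v = np.asarray(v_l, dtype=np.float32)
        scale = ops["scale"] if v.ndim == 1 else ops["scale"][:, None]
        return scale * (ops["le"] @ v)

    def exc_to_global(self, v_e: np.ndarray) -> np.ndarray:
        """sum_j J^{EG}_ij V^E_j (source factors under ``balance_mode
        "both"``, unit weights otherwise)."""
        return self._ops()["eg_scaled"] @ np.asarray(v_e, dtype=np.float32)

    def exc_to_local(self, v_e: np.ndarray) -> np.ndarray:
        """sum_j J^{EL}_ij V^E_j into each local inhibitory neuron."""
        return self._ops()["el_scaled"] @ np.asarray(v_e, dtype=np.float32)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_patterns(n_e: int, p: int, f: float, seed) -> PatternMatrix:
    """Draw p i.i.d. Bernoulli(f) membership vectors of length N_E."""
    if not 0 < f < 1:
        raise ValueError(f"sparseness f must lie in (0,1), got {f}")
    if n_e < 1 or p < 1:
        raise ValueError("N_E and p must be >= 1")
    rng = np.random.default_rng(seed)
    xi = sp.csr_matrix(rng.random((p, n_e)) < f, dtype=np.float64)
    return PatternMatrix(xi=xi, li_members=[], f=f,
                         seed=seed if isinstance(seed, int) else None)


def assign_local_inhibitory(n_l: int, p: int, n_li: int, seed) -> list[np.ndarray]:
    """Sample each pattern's local-inhibitory pool: n_li ids drawn
    uniformly without replacement from 0..N_L-1, independently per pattern."""
    if n_li > n_l:
        raise ValueError(f"n_li={n_li} exceeds N_L={n_l}")
    rng = np.random.default_rng(seed)
    return [np.sort(rng.choice(n_l, size=n_li, replace=False)) for _ in range(p)]


def generate_patterns(n_e: int, p: int, f: float, n_l: int, n_li: int,
                      seed) -> PatternMatrix:
    """Sample excitatory membership and local-inhibitory pools together."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_xi, s_li = ss.spawn(2)
    pm = sample_patterns(n_e, p, f, s_xi)
    pm.li_members = assign_local_inhibitory(n_l, p, n_li, s_li)
    pm.seed = seed if isinstance(seed, int) else None
    return pm


def build_association_weights(patterns: PatternMatrix, graph: MemoryGraph):
    """Association weights T = xi^T (I + A) xi (extended association rule).

    Dense ndarray for N_E <= 8000, CSR above.
    """
    if patterns.p != graph.p:
        raise ValueError(
            f"pattern count {patterns.p} != graph vertex count {graph.p}")
    assoc = (sp.identity(graph.p, format="csr") + graph.adjacency()).tocsr()
    xi = patterns.xi.astype(np.float64)
    t = (xi.T @ (assoc @ xi)).tocsr()
    return t.toarray() if patterns.n_e <= _DENSE_T_LIMIT else t


def sample_connectivity(n_e: int, n_g: int, p_eg: float, p_ge: float,
                        seed) -> ConnectivityMasks:
    """Independent Bernoulli masks between excitatory and global pools."""
    for name, prob in (("p_eg", p_eg), ("p_ge", p_ge)):
        if not 0 <= prob <= 1:
            raise ValueError(f"{name} must lie in [0,1], got {prob}")
    rng = np.random.default_rng(seed)
    ge = (rng.random((n_e, n_g)) < p_eg).astype(np.uint8)
    eg = sp.csr_matrix(rng.random((n_g, n_e)) < p_ge, dtype=np.float64)
    return ConnectivityMasks(ge_mask=ge, eg_mask=eg, p_eg=p_eg, p_ge=p_ge,
                             seed=seed if isinstance(seed, int) else None)


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

def _balance_from_rowsums(rowsum: np.ndarray) -> np.ndarray:
    mean = rowsum.mean()
    if mean <= 0:
        raise ValueError("degenerate network: association matrix has no weight")
    return rowsum / mean


def balance_weights(T, masks: ConnectivityMasks, patterns: PatternMatrix,
                    graph: MemoryGraph | None = None,
                    balance_mode: str = "incoming") -> WeightSet:
    """Balance cross-population weights from the association matrix T.

    Each excitatory neuron's balancing factor is its presynaptic input sum
    in T (off-diagonal row sum, matching the j != i sum of the current
    equation) divided by the population mean of those sums; the factors
    therefore average exactly 1. The factor of neuron i becomes the weight
    of every permitted inhibitory->excitatory connection onto i, so the
    inhibition a neuron receives is proportional to the recurrent
    excitation it receives; ``balance_mode="both"`` additionally applies
    the source neuron's factor to every excitatory->inhibitory connection.
    """
    t_arr = T.toarray() if sp.issparse(T) else np.asarray(T)
    t_diag = np.diag(t_arr).copy()
    rowsum = t_arr.sum(axis=1) - t_diag
    scale = _balance_from_rowsums(rowsum)
    if graph is not None:
        assoc = (sp.identity(graph.p, format="csr") + graph.adjacency()).tocsr()
    else:  # patterns alone cannot recover A; apply the explicit T instead
        assoc = None
    n_l = _infer_n_l(patterns)
    ws = WeightSet(patterns=patterns, masks=masks, assoc=assoc,
                   scale=scale, t_diag=t_diag,
                   le_mask=_local_membership_mask(patterns, n_l),
                   balance_mode=balance_mode)
    ws._T = T
    return ws


def _infer_n_l(patterns: PatternMatrix) -> int:
    if not patterns.li_members:
        raise ValueError("patterns carry no local-inhibitory assignment")
    return int(max(m.max() for m in patterns.li_members if m.size)) + 1


def _local_membership_mask(patterns: PatternMatrix, n_l: int) -> sp.csr_matrix:
    """N_E x N_L mask: 1 where neuron and LI neuron share >= 1 pattern."""
    eta = patterns.li_indicator(n_l)
    prod = (patterns.xi.T @ eta).tocsr()
    prod.data = np.ones_like(prod.data)
    return prod


def build_network(graph: MemoryGraph, *, n_e: int, n_g: int, n_l: int,
                  f: float, n_li: int, p_eg: float, p_ge: float,
                  seed, balance_mode: str = "incoming") -> WeightSet:
    """Generate patterns, masks, and balanced weights for one network
    realization, without materializing the N_E x N_E association matrix."""
    ss = np.random.SeedSequence(seed)
    s_pat, s_conn = ss.spawn(2)
    patterns = generate_patterns(n_e, graph.p, f, n_l, n_li, s_pat)
    masks = sample_connectivity(n_e, n_g, p_eg, p_ge, s_conn)
    assoc = (sp.identity(graph.p, format="csr") + graph.adjacency()).tocsr()
    xi = patterns.xi
    s_xi = (assoc @ xi).tocsr()
    t_diag = np.asarray(xi.multiply(s_xi).sum(axis=0)).ravel()
    rowsum = np.asarray(xi.T @ (s_xi @ np.ones(n_e))).ravel() - t_diag
    scale = _balance_from_rowsums(rowsum)
    return WeightSet(patterns=patterns, masks=masks, assoc=assoc, scale=scale,
                     t_diag=t_diag,
                     le_mask=_local_membership_mask(patterns, n_l),
                     balance_mode=balance_mode)


# ---------------------------------------------------------------------------
# persistence (HDF5)
# ---------------------------------------------------------------------------

def save_patterns(patterns: PatternMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        g = h5.create_group("patterns")
        g.attrs["f"] = patterns.f
        if patterns.seed is not None:
            g.attrs["seed"] = patterns.seed
        g.create_dataset("xi_indptr", data=patterns.xi.indptr)
        g.create_dataset("xi_indices", data=patterns.xi.indices)
        g.attrs["shape"] = patterns.xi.shape
        li = g.create_group("li_members")
        for mu, mem in enumerate(patterns.li_members):
            li.create_dataset(str(mu), data=mem)


def load_patterns(path: str | Path) -> PatternMatrix:
    with h5py.File(path, "r") as h5:
        g = h5["patterns"]
        shape = tuple(g.attrs["shape"])
        indptr = g["xi_indptr"][...]
        indices = g["xi_indices"][...]
        xi = sp.csr_matrix((np.ones(indices.size), indices, indptr), shape=shape)
        li = [g["li_members"][str(mu)][...] for mu in range(shape[0])]
        seed = int(g.attrs["seed"]) if "seed" in g.attrs else None
        return PatternMatrix(xi=xi, li_members=li, f=float(g.attrs["f"]), seed=seed)
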