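"""Associative memory structures: graphs whose vertices are memory patterns.

A memory structure M = (P, A) has p pattern-vertices and undirected
association edges. This module builds the structures used throughout the
package (ring chain, K5-3-chain, Zachary karate club, Tutte, multiroom),
loads user-supplied graphs from edge lists or GraphML, and provides the
topological queries the analysis layer needs: all-pairs hop distances,
closed d-neighborhoods (local areas), and seeded label-propagation
community detection.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

__all__ = [
    "MemoryGraph",
    "CommunityLabels",
    "LocalArea",
    "build_ring_chain",
    "build_k5_chain",
    "build_karate",
    "build_tutte",
    "build_multiroom",
    "shortest_path_matrix",
    "diameter",
    "closed_neighborhood",
    "label_propagation",
    "load_graph",
    "save_graph",
    "TUTTE_CENTRAL_VERTEX",
]

#: Vertex adjoining the three "rooms" of the Tutte graph, in the vertex
#: numbering of the shipped edge list (which follows the standard published
#: construction). It is the unique fixed point of the graph's 3-fold
#: rotational symmetry; a test asserts this identification.
TUTTE_CENTRAL_VERTEX = 0


@dataclass(frozen=True)
class MemoryGraph:
    """An undirected, connected, simple graph with vertices 0..p-1.

    Parameters
    ----------
    p : number of pattern-vertices.
    edges : unordered vertex pairs, stored with the smaller id first.
    name : human-readable label.
    metadata : constructor parameters (room size, doorway ids, ...).
    """

    p: int
    edges: tuple[tuple[int, int], ...]
    name: str = ""
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("graph needs at least one vertex")
        canon = []
        seen = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at vertex {u}")
            if not (0 <= u < self.p and 0 <= v < self.p):
                raise ValueError(f"edge ({u},{v}) outside 0..{self.p - 1}")
            e = (min(u, v), max(u, v))
            if e in seen:
                raise ValueError(f"duplicate edge {e}")
            seen.add(e)
            canon.append(e)
        object.__setattr__(self, "edges", tuple(sorted(canon)))
        g = self.to_networkx()
        if self.p > 1 and not nx.is_connected(g):
            raise ValueError("memory graph must be connected")

    # -- queries ---------------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.p))
        g.add_edges_from(self.edges)
        return g

    def adjacency(self) -> csr_matrix:
        """Symmetric 0/1 adjacency matrix (p x p, CSR)."""
        if not self.edges:
            return csr_matrix((self.p, self.p))
        rows, cols = zip(*self.edges)
        r = np.array(rows + cols)
        c = np.array(cols + rows)
        return csr_matrix((np.ones(r.size), (r, c)), shape=(self.p, self.p))

    def neighbors(self, v: int) -> np.ndarray:
        """The neighbor set K of pattern-vertex v."""
        self._check_vertex(v)
        return np.array(sorted(
            {b for a, b in self.edges if a == v} | {a for a, b in self.edges if b == v}
        ), dtype=int)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.p, dtype=int)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def _check_vertex(self, v: int) -> None:
        if not 0 <= v < self.p:
            raise ValueError(f"unknown vertex {v}")


@dataclass(frozen=True)
class CommunityLabels:
    """Integer community id per vertex, from seeded label propagation."""

    labels: np.ndarray
    seed: int

    @property
    def n_communities(self) -> int:
        return int(np.unique(self.labels).size)

    def agreement_sign(self) -> np.ndarray:
        """Matrix of +1 (same community) / -1 (different), p x p."""
        same = self.labels[:, None] == self.labels[None, :]
        return np.where(same, 1.0, -1.0)


@dataclass(frozen=True)
class LocalArea:
    """Closed d-neighborhood of a vertex: everything within d hops."""

    center: int
    radius: int
    members: frozenset[int]

    def sign(self, p: int) -> np.ndarray:
        """Vector of +1 for members, -1 otherwise, length p."""
        s = -np.ones(p)
        s[list(self.members)] = 1.0
        return s


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def build_ring_chain(p: int) -> MemoryGraph:
    """1D chain of p patterns: every vertex adjacent to exactly two others.

    The only simple connected graph in which each vertex has exactly two
    neighbors is a cycle, so the chain closes into a ring; distances along
    it are taken modulo p.
    """
    if p < 3:
        raise ValueError("a ring chain needs p >= 3")
    edges = tuple((i, (i + 1) % p) for i in range(p))
    return MemoryGraph(p, edges, name=f"ring-{p}", metadata={"kind": "ring"})


def build_k5_chain() -> MemoryGraph:
    """Three near-complete 5-vertex fragments chained into one graph.

    Each fragment is a K5 with the edge between its two boundary vertices
    removed; the freed boundary vertices are wired cyclically between the
    fragments (fragment i -> fragment i+1 mod 3), which keeps every vertex
    at degree 4 and gives the structure diameter 4.
    """
    edges: list[tuple[int, int]] = []
    for frag in range(3):
        base = 5 * frag
        verts = range(base, base + 5)
        for a in verts:
            for b in verts:
                if a < b and not (a == base and b == base + 1):
                    edges.append((a, b))
    # boundary vertex base+1 of fragment i links to boundary vertex base of
    # fragment i+1
    for frag in range(3):
        edges.append((5 * frag + 1, 5 * ((frag + 1) % 3)))
    return MemoryGraph(15, tuple(edges), name="k5-3-chain",
                       metadata={"boundary": [(5 * i, 5 * i + 1) for i in range(3)]})


def _load_fixture(stem: str) -> list[tuple[int, int]]:
    ref = importlib.resources.files("assocmem.data") / f"{stem}.edgelist"
    edges = []
    for line in ref.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            u, v = line.split()
            edges.append((int(u), int(v)))
    return edges


def build_karate() -> MemoryGraph:
    """Zachary's karate club graph (34 practitioners, 78 interactions)."""
    return MemoryGraph(34, tuple(_load_fixture("karate")), name="karate")


def build_tutte() -> MemoryGraph:
    """The Tutte graph: 3-regular, 46 vertices, no Hamiltonian cycle.

    Vertex :data:`TUTTE_CENTRAL_VERTEX` adjoins the three "rooms".
    """
    return MemoryGraph(46, tuple(_load_fixture("tutte")), name="tutte",
                       metadata={"central_vertex": TUTTE_CENTRAL_VERTEX})


def build_multiroom(room_side: int = 5, doorway_pos: int | None = None) -> MemoryGraph:
    """Four square grid rooms joined in a cycle through doorway vertices.

    Rooms sit at the corners of a 2x2 layout; each pair of adjacent rooms
    shares one dedicated doorway vertex attached to the middle cell of the
    facing wall of each room (``doorway_pos`` selects the wall cell; default
    is the center). Removing the four doorway vertices disconnects the
    rooms, and each room communicates with exactly two others.
    """
    s = room_side
    if s < 2:
        raise ValueError("room_side must be >= 2")
    m = (s - 1) // 2 if doorway_pos is None else doorway_pos
    if not 0 <= m < s:
        raise ValueError(f"doorway position {m} outside wall 0..{s - 1}")

    def vid(room: int, r: int, c: int) -> int:
        return room * s * s + r * s + c

    edges: list[tuple[int, int]] = []
    for room in range(4):
        for r in range(s):
            for c in range(s):
                if r + 1 < s:
                    edges.append((vid(room, r, c), vid(room, r + 1, c)))
                if c + 1 < s:
                    edges.append((vid(room, r, c), vid(room, r, c + 1)))
    doors = [4 * s * s + k for k in range(4)]
    # cycle R0 -R1 -R2 -R3 -R0; wall-middle attachment cells per pair
    attach = [
        (vid(0, m, s - 1), vid(1, m, 0)),        # R0 right wall <-> R1 left wall
        (vid(1, s - 1, m), vid(2, 0, m)),        # R1 bottom <-> R2 top
        (vid(2, m, 0), vid(3, m, s - 1)),        # R2 left <-> R3 right
        (vid(3, 0, m), vid(0, s - 1, m)),        # R3 top <-> R0 bottom
    ]
    for door, (a, b) in zip(doors, attach):
        edges.append((a, door))
        edges.append((door, b))
    meta = {
        "room_side": s,
        "doorway_pos": m,
        "doorways": doors,
        "near_doorway_vertex": attach[0][0],
    }
    return MemoryGraph(4 * s * s + 4, tuple(edges), name=f"multiroom-{s}", metadata=meta)


# ---------------------------------------------------------------------------
# topological queries
# ---------------------------------------------------------------------------

def shortest_path_matrix(graph: MemoryGraph) -> np.ndarray:
    """All-pairs hop distances (p x p int matrix) via BFS."""
    dist = _csgraph_shortest_path(graph.adjacency(), method="D", unweighted=True)
    if np.isinf(dist).any():
        raise ValueError("graph has unreachable vertices")
    return dist.astype(int)


def diameter(graph: MemoryGraph) -> int:
    return int(shortest_path_matrix(graph).max())


def closed_neighborhood(graph: MemoryGraph, v: int, d: int,
                        dist: np.ndarray | None = None) -> LocalArea:
    """Local area LA: the vertex v plus all vertices within d hops of it."""
    graph._check_vertex(v)
    if d < 0:
        raise ValueError("radius must be >= 0")
    if dist is None:
        dist = shortest_path_matrix(graph)
    members = frozenset(np.flatnonzero(dist[v] <= d).tolist())
    return LocalArea(center=v, radius=d, members=members)


def label_propagation(graph: MemoryGraph, seed: int) -> CommunityLabels:
    """Seeded asynchronous label propagation community detection.

    Vertices are visited in a seeded random order and adopt the most
    frequent label among their neighbors, ties broken at random, until
    every vertex carries one of its neighborhood's majority labels. One
    run per call (no consensus clustering).
    """
    communities = nx.community.asyn_lpa_communities(graph.to_networkx(), seed=seed)
    labels = np.empty(graph.p, dtype=int)
    for cid, members in enumerate(communities):
        labels[list(members)] = cid
    return CommunityLabels(labels=labels, seed=seed)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_graph(path: str | Path, name: str | None = None) -> MemoryGraph:
    """Load a graph from a whitespace edge list (0-based ids) or GraphML."""
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.read_graphml(path)
        g = nx.relabel_nodes(g, {n: int(n) for n in g.nodes})
        p = g.number_of_nodes()
        edges = tuple((int(u), int(v)) for u, v in g.edges)
    else:
        edges_l = []
        p = 0
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            u, v = (int(tok) for tok in line.split()[:2])
            edges_l.append((u, v))
            p = max(p, u + 1, v + 1)
        edges = tuple(edges_l)
    return MemoryGraph(p, edges, name=name or path.stem)


def save_graph(graph: MemoryGraph, path: str | Path) -> None:
    """Write a graph as GraphML or a plain edge list, by file extension."""
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(graph.to_networkx(), path)
    else:
        lines = [f"{u} {v}" for u, v in graph.edges]
        path.write_text("\n".join(lines) + "\n")


BUILTIN_GRAPHS = {
    "ring": build_ring_chain,
    "k5-3-chain": build_k5_chain,
    "karate": build_karate,
    "tutte": build_tutte,
    "multiroom": build_multiroom,
}


def build_graph(spec: str | dict) -> MemoryGraph:
    """Build a graph from a name, a ``{name: ..., params: {...}}`` mapping,
    or a file path."""
    if isinstance(spec, dict):
        name = spec["name"]
        params = spec.get("params", {})
    else:
        name, params = spec, {}
    if name in BUILTIN_GRAPHS:
        return BUILTIN_GRAPHS[name](**params)
    if Path(name).exists():
        return load_graph(name)
    raise ValueError(f"unknown graph {name!r}; builtins: {sorted(BUILTIN_GRAPHS)}")
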