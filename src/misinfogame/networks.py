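"""Network substrates for the news-sharing game.

The simulator runs on three families of undirected simple graphs: square
lattices (von Neumann or Moore neighborhoods, periodic by default so that
every vertex is equivalent), Watts–Strogatz small worlds, and empirical
edge lists in the SNAP dialect (whitespace-separated integer pairs,
``#``-prefixed comments).  Centrality scores used for targeted sanctioner
placement live here as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence, TextIO

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc

__all__ = [
    "Graph",
    "NetworkSpec",
    "GraphSpecError",
    "EdgeListParseError",
    "EmptyEdgeListError",
    "SmallWorld",
    "EdgeListGraph",
    "make_lattice",
    "make_small_world",
    "read_edge_list",
    "write_edge_list",
    "degree_scores",
    "betweenness_scores",
    "components",
]


class GraphSpecError(ValueError):
    """A network specification violates its preconditions."""


class EdgeListParseError(ValueError):
    """An edge-list stream contains a malformed line."""


class EmptyEdgeListError(ValueError):
    """An edge-list stream contained no vertices."""


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph in compressed sparse row form.

    Nodes are indexed ``0..n-1``; ``indices[indptr[i]:indptr[i+1]]`` is the
    sorted neighbor list of node ``i``.  Symmetry (``j in adj(i)`` iff
    ``i in adj(j)``), absence of self-loops and of duplicate neighbors are
    construction invariants, checked by :meth:`validate`.
    """

    indptr: np.ndarray
    indices: np.ndarray

    @property
    def n(self) -> int:
        return len(self.indptr) - 1

    @property
    def num_edges(self) -> int:
        return len(self.indices) // 2

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    @property
    def is_regular(self) -> bool:
        deg = self.degrees
        return self.n > 0 and bool((deg == deg[0]).all())

    @property
    def k(self) -> int:
        """Common degree of a regular graph."""
        if not self.is_regular:
            raise GraphSpecError("graph is not regular; k is undefined")
        return int(self.degrees[0])

    @classmethod
    def from_edges(cls, n: int, edges: Iterable[tuple[int, int]]) -> "Graph":
        """Build from an iterable of (u, v) pairs.

        Direction, duplicates and self-loops are dropped.
        """
        pairs = {(min(u, v), max(u, v)) for u, v in edges if u != v}
        us = np.fromiter((u for u, _ in pairs), dtype=np.int64, count=len(pairs))
        vs = np.fromiter((v for _, v in pairs), dtype=np.int64, count=len(pairs))
        src = np.concatenate([us, vs])
        dst = np.concatenate([vs, us])
        order = np.lexsort((dst, src))
        src, dst = src[order], dst[order]
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(indptr, src + 1, 1)
        np.cumsum(indptr, out=indptr)
        return cls(indptr=indptr, indices=dst.astype(np.int64))

    @classmethod
    def from_adjacency_sets(cls, adj: Sequence[set]) -> "Graph":
        indptr = np.zeros(len(adj) + 1, dtype=np.int64)
        chunks = []
        for i, nbrs in enumerate(adj):
            indptr[i + 1] = indptr[i] + len(nbrs)
            chunks.append(np.fromiter(sorted(nbrs), dtype=np.int64, count=len(nbrs)))
        indices = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
        return cls(indptr=indptr, indices=indices)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges())
        return g

    def to_sparse(self) -> sp.csr_matrix:
        data = np.ones(len(self.indices), dtype=np.int8)
        return sp.csr_matrix((data, self.indices, self.indptr), shape=(self.n, self.n))

    def edges(self) -> Iterable[tuple[int, int]]:
        """Each undirected edge once, with u < v."""
        for u in range(self.n):
            for v in self.neighbors(u):
                if u < v:
                    yield int(u), int(v)

    def validate(self) -> None:
        n = self.n
        for u in range(n):
            nbrs = self.neighbors(u)
            if len(nbrs) and (np.diff(nbrs) <= 0).any():
                raise GraphSpecError(f"neighbor list of {u} not strictly sorted")
            if (nbrs == u).any():
                raise GraphSpecError(f"self-loop at {u}")
            if (nbrs < 0).any() or (nbrs >= n).any():
                raise GraphSpecError(f"neighbor index out of range at {u}")
        a = self.to_sparse()
        if (a != a.T).nnz:
            raise GraphSpecError("adjacency is not symmetric")


def make_lattice(
    rows: int,
    cols: int,
    neighborhood: str = "von_neumann",
    periodic: bool = True,
) -> Graph:
    """Square lattice; node index = row * cols + col.

    The periodic von Neumann lattice is 4-regular; Moore adds the four
    diagonal neighbors (8-regular).  Periodic wrap-around requires at least
    three rows and columns, otherwise wrapping would create duplicate or
    self edges.
    """
    if rows < 1 or cols < 1:
        raise GraphSpecError("lattice dimensions must be positive")
    if periodic and (rows < 3 or cols < 3):
        raise GraphSpecError("periodic lattice requires rows >= 3 and cols >= 3")
    if neighborhood == "von_neumann":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif neighborhood == "moore":
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        raise GraphSpecError(f"unknown neighborhood {neighborhood!r}")
    edges = []
    for r in range(rows):
        for c in range(cols):
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if periodic:
                    rr, cc = rr % rows, cc % cols
                elif not (0 <= rr < rows and 0 <= cc < cols):
                    continue
                edges.append((r * cols + c, rr * cols + cc))
    return Graph.from_edges(rows * cols, edges)


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of a network substrate.

    ``family`` selects the generator: ``lattice`` (rows x cols, von
    Neumann or Moore neighborhood, periodic by default), ``small_world``
    (Watts–Strogatz with n nodes, even base degree and rewiring
    probability) or ``edge_list`` (SNAP-dialect file at ``path``,
    symmetrized on read).
    """

    family: str = "lattice"
    rows: int = 30
    cols: int = 30
    neighborhood: str = "von_neumann"
    periodic: bool = True
    n: int = 900
    base_degree: int = 8
    rewire_prob: float = 0.03
    path: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("lattice", "small_world", "edge_list"):
            raise GraphSpecError(f"unknown network family {self.family!r}")
        if self.family == "small_world":
            if self.base_degree % 2 or self.base_degree >= self.n:
                raise GraphSpecError("base_degree must be even and < n")
            if not 0.0 <= self.rewire_prob <= 1.0:
                raise GraphSpecError("rewire_prob must lie in [0, 1]")
        if self.family == "edge_list" and not self.path:
            raise GraphSpecError("edge_list family requires a path")

    def build(self, seed: Optional[int] = None) -> Graph:
        if self.family == "lattice":
            return make_lattice(self.rows, self.cols, self.neighborhood, self.periodic)
        if self.family == "small_world":
            return make_small_world(
                self.n, self.base_degree, self.rewire_prob,
                seed=self.seed if seed is None else seed,
            ).graph
        with open(self.path) as fh:
            return read_edge_list(fh).graph

    @property
    def is_random(self) -> bool:
        return self.family == "small_world"


class SmallWorld(NamedTuple):
    graph: Graph
    n_rewired: int


def make_small_world(
    n: int,
    base_degree: int,
    rewire_prob: float,
    seed: int | np.random.Generator = 0,
    convention: str = "per_stub",
) -> SmallWorld:
    """Watts–Strogatz small world; returns the graph and the rewire count.

    Starts from a ring lattice where every node links to ``base_degree/2``
    neighbors on each side.  Under the default ``per_stub`` convention each
    undirected ring edge receives two independent rewiring considerations,
    one anchored at each endpoint: a firing consideration keeps the
    anchored endpoint and redraws the other uniformly, avoiding self-loops
    and duplicates.  Each of the ``n * base_degree`` stubs therefore fires
    with probability ``rewire_prob``, so the expected number of rewired
    edges is ``n * base_degree * rewire_prob``.  The common single-pass
    convention (one consideration per edge, anchored at the lower endpoint;
    expectation half as large) is available as ``convention="one_pass"``.

    When no admissible rewiring target exists (dense graphs), that rewire
    is skipped with a warning.  Degree sum is conserved.
    """
    if base_degree % 2:
        raise GraphSpecError("base_degree must be even")
    if base_degree >= n:
        raise GraphSpecError("base_degree must be < n")
    if not 0.0 <= rewire_prob <= 1.0:
        raise GraphSpecError("rewire_prob must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half = base_degree // 2
    adj: list[set] = [set() for _ in range(n)]
    slots = []  # current endpoints of each original ring edge
    for i in range(n):
        for d in range(1, half + 1):
            j = (i + d) % n
            adj[i].add(j)
            adj[j].add(i)
            slots.append([i, j])

    n_rewired = 0
    skipped = 0
    passes = (0, 1) if convention == "per_stub" else (0,)
    if convention not in ("per_stub", "one_pass"):
        raise GraphSpecError(f"unknown rewiring convention {convention!r}")
    for anchor_side in passes:
        for slot in slots:
            if rng.random() >= rewire_prob:
                continue
            keep, drop = slot[anchor_side], slot[1 - anchor_side]
            # uniform new partner avoiding self, current neighbors
            target = -1
            for _ in range(4 * n):
                cand = int(rng.integers(n))
                if cand != keep and cand not in adj[keep]:
                    target = cand
                    break
            if target < 0:
                skipped += 1
                continue
            adj[keep].discard(drop)
            adj[drop].discard(keep)
            adj[keep].add(target)
            adj[target].add(keep)
            slot[anchor_side], slot[1 - anchor_side] = keep, target
            n_rewired += 1
    if skipped:
        warnings.warn(
            f"skipped {skipped} rewires: no admissible target (graph too dense)",
            stacklevel=2,
        )
    return SmallWorld(Graph.from_adjacency_sets(adj), n_rewired)


class EdgeListGraph(NamedTuple):
    graph: Graph
    id_map: dict  # original id -> contiguous index


def read_edge_list(stream: TextIO | Iterable[str], directed_input: bool = True) -> EdgeListGraph:
    """Read a SNAP-dialect edge list and symmetrize it.

    Lines are ``"u v"`` integer pairs; lines starting with ``#`` (and blank
    lines) are ignored.  Node ids need not be contiguous: they are remapped
    to ``0..n-1`` in sorted order and the mapping is returned.  Direction is
    dropped; duplicate and reciprocal pairs collapse; self-loops are
    removed (their endpoints still count as vertices).
    """
    raw_edges = []
    ids = set()
    for lineno, line in enumerate(stream, start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        parts = text.split()
        if len(parts) != 2:
            raise EdgeListParseError(f"line {lineno}: expected two tokens, got {len(parts)}")
        try:
            u, v = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise EdgeListParseError(f"line {lineno}: non-integer token") from exc
        ids.update((u, v))
        raw_edges.append((u, v))
    if not ids:
        raise EmptyEdgeListError("edge-list stream contained no vertices")
    id_map = {orig: idx for idx, orig in enumerate(sorted(ids))}
    edges = [(id_map[u], id_map[v]) for u, v in raw_edges]
    return EdgeListGraph(Graph.from_edges(len(ids), edges), id_map)


def write_edge_list(graph: Graph, stream: TextIO) -> None:
    """Write one ``"u v"`` line per undirected edge (u < v)."""
    for u, v in graph.edges():
        stream.write(f"{u} {v}\n")


def degree_scores(graph: Graph) -> np.ndarray:
    """Per-node degree, the simplest centrality used for targeting."""
    return graph.degrees.astype(np.float64)


def betweenness_scores(
    graph: Graph,
    sample_sources: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Shortest-path betweenness (Brandes accumulation via networkx).

    Exact when ``sample_sources`` is None; otherwise an unbiased
    source-sampled estimate rescaled to the exact range (with all ``n``
    sources the estimate coincides with the exact values).  Unnormalized
    convention: each unordered dependent pair contributes 1.  Disconnected
    graphs are handled per component by the shortest-path machinery itself.

    Graphs beyond 20,000 nodes (e.g. large follower networks) fall back
    automatically to a 2,000-source seeded estimate; pass
    ``sample_sources=n`` to force the exact computation.
    """
    g = graph.to_networkx()
    if sample_sources is None and graph.n > 20_000:
        sample_sources = 2_000
    if sample_sources is not None and sample_sources > graph.n:
        warnings.warn(
            f"sample_sources={sample_sources} exceeds n={graph.n}; clamped",
            stacklevel=2,
        )
        sample_sources = graph.n
    scores = nx.betweenness_centrality(
        g, k=sample_sources, normalized=False, seed=np.random.RandomState(seed)
    )
    return np.array([scores[i] for i in range(graph.n)], dtype=np.float64)


def components(graph: Graph, node_subset: Iterable[int] | None = None) -> list[np.ndarray]:
    """Connected components of the induced subgraph on ``node_subset``.

    Returned as sorted member arrays, ordered by decreasing size with ties
    broken by smallest member id.
    """
    if node_subset is None:
        nodes = np.arange(graph.n)
    else:
        nodes = np.fromiter(sorted(set(int(i) for i in node_subset)), dtype=np.int64)
        if len(nodes) and (nodes[0] < 0 or nodes[-1] >= graph.n):
            raise GraphSpecError("node_subset contains out-of-range ids")
    if len(nodes) == 0:
        return []
    sub = graph.to_sparse()[nodes][:, nodes]
    ncomp, labels = _cc(sub, directed=False)
    comps = [nodes[labels == c] for c in range(ncomp)]
    comps.sort(key=lambda m: (-len(m), int(m[0])))
    return comps
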