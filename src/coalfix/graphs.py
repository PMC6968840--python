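"""Weighted-graph model of spatially structured populations.

Population structure is a connected, weighted, undirected graph ``G`` on
``N`` vertices, one haploid individual per vertex.  Edge weight ``w_ij >= 0``
measures the strength of the spatial coupling between vertices ``i`` and
``j``; ``w_ij = w_ji`` and self-loops are excluded (``w_ii = 0``).

Derived quantities used throughout the package:

* weighted degree            ``w_i = sum_j w_ij``
* random-walk step matrix    ``p_ij = w_ij / w_i``
* stationary distribution    ``pi_i = w_i / sum_j w_j``

A graph is *isothermal* when every vertex has the same weighted degree,
i.e. the stationary distribution is uniform.

This module provides the graph container, deterministic family
constructors (complete, star, cycle, Fan, Separated Hubs, Star of
Islands), seeded random-graph generators (Erdős–Rényi, Barabási–Albert,
random regular), degree statistics, and edge-list / JSON input-output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GraphError",
    "InvalidSizeError",
    "InvalidParameterError",
    "DisconnectedGraphError",
    "DegenerateVertexError",
    "EdgeListFormatError",
    "WeightedGraph",
    "DegreeMoments",
    "make_complete",
    "make_star",
    "make_cycle",
    "make_fan",
    "make_separated_hubs",
    "make_star_of_islands",
    "make_erdos_renyi",
    "make_barabasi_albert",
    "make_random_regular",
    "weighted_degrees",
    "step_probabilities",
    "stationary_distribution",
    "is_isothermal",
    "degree_moments",
    "read_edgelist",
    "write_edgelist",
    "graph_to_json",
    "graph_from_json",
]

#: Hard cap on dense weight storage; the pairwise coalescence system has
#: N(N-1)/2 unknowns, which caps the practical graph size anyway.
MAX_DENSE_N = 2000


class GraphError(ValueError):
    """Base class for graph-construction and graph-validation errors."""


class InvalidSizeError(GraphError):
    """Requested graph size is outside the constructor's valid range."""


class InvalidParameterError(GraphError):
    """A structural parameter (edge weight, probability, ...) is invalid."""


class DisconnectedGraphError(GraphError):
    """Operation requires a connected graph."""


class DegenerateVertexError(GraphError):
    """A vertex has zero weighted degree (isolated vertex)."""


class EdgeListFormatError(GraphError):
    """Malformed edge-list file."""


@dataclass
class WeightedGraph:
    """Symmetric nonnegative edge-weight matrix on ``N`` vertices.

    Parameters
    ----------
    w
        ``(N, N)`` array of edge weights.  Must be symmetric, nonnegative,
        with zero diagonal.
    meta
        Optional provenance (family name, construction parameters, seed,
        redraw counts).  Not used in any computation.
    """

    w: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise GraphError("weight matrix must be square")
        if w.shape[0] < 2:
            raise InvalidSizeError("a population needs at least 2 vertices")
        if w.shape[0] > MAX_DENSE_N:
            raise InvalidSizeError(
                f"graphs larger than N={MAX_DENSE_N} are not supported"
            )
        if np.any(w < 0):
            raise GraphError("edge weights must be nonnegative")
        if not np.array_equal(w, w.T):
            raise GraphError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise GraphError("self-loops are not allowed (w_ii must be 0)")
        self.w = w

    @property
    def N(self) -> int:
        """Number of vertices (= population size)."""
        return self.w.shape[0]

    def is_connected(self) -> bool:
        """True if the graph restricted to positive weights is connected."""
        adj = csr_matrix(self.w > 0)
        n_comp, _ = connected_components(adj, directed=False)
        return n_comp == 1

    def require_connected(self) -> None:
        if not self.is_connected():
            raise DisconnectedGraphError("graph is not connected")

    def edges(self) -> Iterator[tuple[int, int, float]]:
        """Yield each undirected positive-weight edge once as (u, v, w_uv)."""
        iu, ju = np.nonzero(np.triu(self.w) > 0)
        for u, v in zip(iu.tolist(), ju.tolist()):
            yield u, v, float(self.w[u, v])

    def copy(self) -> "WeightedGraph":
        return WeightedGraph(self.w.copy(), meta=dict(self.meta))


@dataclass(frozen=True)
class DegreeMoments:
    """First two moments of the weighted degree distribution.

    ``mu1 = (1/N) sum_i w_i`` and ``mu2 = (1/N) sum_i w_i^2``; variance
    nonnegativity forces ``mu2 >= mu1**2``.
    """

    mu1: float
    mu2: float


# ---------------------------------------------------------------------------
# family constructors
# ---------------------------------------------------------------------------

def make_complete(N: int) -> WeightedGraph:
    """Complete graph ``K_N`` (the well-mixed population), unit weights."""
    if N < 2:
        raise InvalidSizeError("complete graph needs N >= 2")
    w = np.ones((N, N)) - np.eye(N)
    return WeightedGraph(w, meta={"family": "complete", "N": N})


def make_star(n: int) -> WeightedGraph:
    """Star ``S_n``: hub (vertex 0) joined to ``n`` leaves, unit weights."""
    if n < 2:
        raise InvalidSizeError("star graph needs n >= 2 leaves")
    N = n + 1
    w = np.zeros((N, N))
    w[0, 1:] = 1.0
    w[1:, 0] = 1.0
    return WeightedGraph(w, meta={"family": "star", "n": n})


def make_cycle(N: int) -> WeightedGraph:
    """Cycle ``C_N``: vertex ``i`` joined to ``i +/- 1 (mod N)``, unit weights."""
    if N < 3:
        raise InvalidSizeError("cycle needs N >= 3")
    w = np.zeros((N, N))
    idx = np.arange(N)
    w[idx, (idx + 1) % N] = 1.0
    w[(idx + 1) % N, idx] = 1.0
    return WeightedGraph(w, meta={"family": "cycle", "N": N})


def make_fan(n: int, m: int, eps: float) -> WeightedGraph:
    """Fan ``F_{n,m}``: one hub and ``n`` blades of ``m`` vertices each.

    The hub (vertex 0) is joined to every blade vertex with weight ``eps``;
    vertices on the same blade are pairwise joined with weight 1.  The Fan
    is isothermal exactly when ``eps = (m - 1)/(n*m - 1)``.

    ``eps = 0`` disconnects the graph and is rejected; the ``eps -> 0``
    limit is available through the closed forms in
    :mod:`coalfix.coalescence` and :mod:`coalfix.exact`.
    """
    if n < 2 or m < 2:
        raise InvalidSizeError("Fan needs n >= 2 blades and m >= 2 vertices each")
    if eps <= 0:
        raise InvalidParameterError("Fan hub-blade weight eps must be > 0")
    N = n * m + 1
    w = np.zeros((N, N))
    w[0, 1:] = eps
    w[1:, 0] = eps
    for b in range(n):
        lo, hi = 1 + b * m, 1 + (b + 1) * m
        w[lo:hi, lo:hi] = 1.0
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(w, meta={"family": "fan", "n": n, "m": m, "eps": eps})


def make_separated_hubs(n: int, m: int, h: int, eps: float) -> WeightedGraph:
    """Separated Hubs ``SH_{n,m,h}``: ``h`` mutually unconnected hubs.

    Hubs occupy vertices ``0..h-1``; each blade vertex is joined to each hub
    with weight ``eps``; within-blade weights are 1.  ``h = 1`` reduces to
    the Fan.
    """
    if n < 2 or m < 2:
        raise InvalidSizeError("Separated Hubs needs n >= 2 and m >= 2")
    if h < 1:
        raise InvalidSizeError("Separated Hubs needs h >= 1 hubs")
    if eps <= 0:
        raise InvalidParameterError("hub-blade weight eps must be > 0")
    N = n * m + h
    w = np.zeros((N, N))
    w[:h, h:] = eps
    w[h:, :h] = eps
    for b in range(n):
        lo, hi = h + b * m, h + (b + 1) * m
        w[lo:hi, lo:hi] = 1.0
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(
        w, meta={"family": "separated_hubs", "n": n, "m": m, "h": h, "eps": eps}
    )


def make_star_of_islands(n: int, m: int, h: int, eps: float) -> WeightedGraph:
    """Star of Islands ``SI_{n,m,h}``: a hub island plus ``n`` islands.

    The hub island (vertices ``0..h-1``) is a clique with unit weights, as
    is each of the ``n`` islands of size ``m``; every hub-island vertex
    pair is joined with weight ``eps``.
    """
    if n < 2 or m < 2:
        raise InvalidSizeError("Star of Islands needs n >= 2 and m >= 2")
    if h < 2:
        raise InvalidSizeError("Star of Islands needs a hub island of h >= 2")
    if eps <= 0:
        raise InvalidParameterError("hub-island weight eps must be > 0")
    N = n * m + h
    w = np.zeros((N, N))
    w[:h, :h] = 1.0
    w[:h, h:] = eps
    w[h:, :h] = eps
    for b in range(n):
        lo, hi = h + b * m, h + (b + 1) * m
        w[lo:hi, lo:hi] = 1.0
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(
        w, meta={"family": "star_of_islands", "n": n, "m": m, "h": h, "eps": eps}
    )


# ---------------------------------------------------------------------------
# random-graph generators
# ---------------------------------------------------------------------------

_MAX_REDRAWS = 10_000


def make_erdos_renyi(
    N: int,
    mean_degree: float,
    seed: int,
    require_connected: bool = True,
) -> WeightedGraph:
    """Erdős–Rényi graph with link probability ``p = mean_degree/(N-1)``.

    Each unordered pair is linked independently with probability ``p``
    (weight 1).  With ``require_connected`` (the default) disconnected
    draws are rejected and redrawn; the number of redraws is recorded in
    ``meta["redraws"]``.
    """
    if N < 2:
        raise InvalidSizeError("Erdős–Rényi graph needs N >= 2")
    p = mean_degree / (N - 1)
    if p <= 0 or p > 1:
        raise InvalidParameterError(
            f"link probability p = <k>/(N-1) = {p:.4g} must lie in (0, 1]"
        )
    rng = np.random.default_rng(seed)
    redraws = 0
    while True:
        upper = rng.random((N, N)) < p
        w = np.triu(upper, k=1).astype(float)
        w = w + w.T
        G = WeightedGraph(
            w,
            meta={
                "family": "erdos_renyi",
                "N": N,
                "mean_degree": mean_degree,
                "p": p,
                "seed": seed,
                "redraws": redraws,
            },
        )
        if not require_connected or G.is_connected():
            return G
        redraws += 1
        if redraws > _MAX_REDRAWS:
            raise DisconnectedGraphError(
                "could not draw a connected Erdős–Rényi graph "
                f"(N={N}, <k>={mean_degree}) in {_MAX_REDRAWS} attempts"
            )


def make_barabasi_albert(N: int, m_links: int, seed: int) -> WeightedGraph:
    """Barabási–Albert preferential-attachment graph.

    Growth starts from a complete graph of size ``m_links + 2``; every new
    vertex attaches ``m_links`` unit-weight edges preferentially by degree.
    ``N = m_links + 2`` returns the complete seed graph itself.
    """
    if m_links < 1:
        raise InvalidParameterError("m_links must be >= 1")
    if N < m_links + 2:
        raise InvalidSizeError("Barabási–Albert needs N >= m_links + 2")
    initial = nx.complete_graph(m_links + 2)
    if N == m_links + 2:
        g = initial
    else:
        g = nx.barabasi_albert_graph(
            N, m_links, seed=int(seed), initial_graph=initial
        )
    w = nx.to_numpy_array(g, nodelist=range(N), weight=None).astype(float)
    return WeightedGraph(
        w,
        meta={
            "family": "barabasi_albert",
            "N": N,
            "m_links": m_links,
            "seed": seed,
        },
    )


def make_random_regular(N: int, k: int, seed: int) -> WeightedGraph:
    """Uniform-ish random ``k``-regular simple graph, connected.

    Generated by the pairing (configuration) model with rejection of
    multi-edges and self-loops (as implemented in networkx), plus
    rejection of disconnected draws.
    """
    if k >= N:
        raise InvalidParameterError("degree k must be < N")
    if (N * k) % 2 != 0:
        raise InvalidParameterError("N*k must be even for a k-regular graph")
    redraws = 0
    while True:
        g = nx.random_regular_graph(k, N, seed=int(seed) + redraws)
        if nx.is_connected(g):
            break
        redraws += 1
        if redraws > _MAX_REDRAWS:
            raise DisconnectedGraphError(
                f"could not draw a connected {k}-regular graph on {N} vertices"
            )
    w = nx.to_numpy_array(g, nodelist=range(N), weight=None).astype(float)
    return WeightedGraph(
        w,
        meta={
            "family": "random_regular",
            "N": N,
            "k": k,
            "seed": seed,
            "redraws": redraws,
        },
    )


# ---------------------------------------------------------------------------
# degree statistics
# ---------------------------------------------------------------------------

def weighted_degrees(G: WeightedGraph) -> np.ndarray:
    """Weighted degrees ``w_i = sum_j w_ij``."""
    return G.w.sum(axis=1)


def step_probabilities(G: WeightedGraph) -> np.ndarray:
    """Random-walk step matrix ``p_ij = w_ij / w_i`` (row-stochastic).

    ``p_ij`` is also the conditional probability, under neutral drift,
    that ``j`` reproduces given that ``i`` is replaced.
    """
    deg = weighted_degrees(G)
    if np.any(deg == 0):
        raise DegenerateVertexError("graph has an isolated vertex (w_i = 0)")
    return G.w / deg[:, None]


def stationary_distribution(G: WeightedGraph) -> np.ndarray:
    """Stationary distribution ``pi_i = w_i / sum_j w_j`` of the walk."""
    G.require_connected()
    deg = weighted_degrees(G)
    return deg / deg.sum()


def is_isothermal(G: WeightedGraph, tol: float = 1e-10) -> bool:
    """True when all weighted degrees agree to relative tolerance ``tol``."""
    deg = weighted_degrees(G)
    if np.any(deg == 0):
        raise DegenerateVertexError("graph has an isolated vertex (w_i = 0)")
    mean = deg.mean()
    return bool(np.max(np.abs(deg - mean)) <= tol * mean)


def degree_moments(G: WeightedGraph) -> DegreeMoments:
    """First and second moments of the weighted degree distribution."""
    deg = weighted_degrees(G)
    return DegreeMoments(mu1=float(deg.mean()), mu2=float((deg**2).mean()))


# ---------------------------------------------------------------------------
# input / output
# ---------------------------------------------------------------------------

def write_edgelist(G: WeightedGraph, path: str | Path) -> None:
    """Write tab-separated rows ``u<TAB>v<TAB>weight``, one per edge.

    Vertices are 0-based; each undirected edge is listed once with
    ``u < v``.  A lone header-free format that round-trips exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# N={G.N}\n")
        for u, v, weight in G.edges():
            fh.write(f"{u}\t{v}\t{weight!r}\n")


def read_edgelist(path: str | Path) -> WeightedGraph:
    """Read a tab-separated edge list written by :func:`write_edgelist`.

    Rows are ``u<TAB>v<TAB>weight`` with 0-based integer vertices.  A
    ``# N=...`` comment fixes the vertex count (otherwise ``max index + 1``
    is used).  Self-loops, negative weights and duplicate edges with
    conflicting weights are rejected; duplicates with equal weights are
    deduplicated.
    """
    path = Path(path)
    edges: dict[tuple[int, int], float] = {}
    n_declared = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "N=" in line:
                    try:
                        n_declared = int(line.split("N=")[1].split()[0])
                    except (ValueError, IndexError) as exc:
                        raise EdgeListFormatError(
                            f"{path}:{lineno}: malformed N= header"
                        ) from exc
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: expected 'u<TAB>v<TAB>weight'"
                )
            try:
                u, v, weight = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise EdgeListFormatError(f"{path}:{lineno}: {exc}") from exc
            if u == v:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: self-loop {u}-{v} not allowed"
                )
            if u < 0 or v < 0:
                raise EdgeListFormatError(f"{path}:{lineno}: negative vertex index")
            if weight < 0:
                raise EdgeListFormatError(f"{path}:{lineno}: negative weight")
            key = (min(u, v), max(u, v))
            if key in edges and edges[key] != weight:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: edge {key} listed twice with "
                    f"conflicting weights {edges[key]} and {weight}"
                )
            edges[key] = weight
    if not edges:
        raise EdgeListFormatError(f"{path}: no edges found")
    n = n_declared if n_declared is not None else max(max(k) for k in edges) + 1
    w = np.zeros((n, n))
    for (u, v), weight in edges.items():
        if u >= n or v >= n:
            raise EdgeListFormatError(f"{path}: vertex index >= declared N={n}")
        w[u, v] = weight
        w[v, u] = weight
    return WeightedGraph(w, meta={"source": str(path)})


def graph_to_json(G: WeightedGraph) -> str:
    """Serialize as ``{"N": int, "edges": [[u, v, w], ...]}``."""
    return json.dumps(
        {"N": G.N, "edges": [[u, v, weight] for u, v, weight in G.edges()]}
    )


def graph_from_json(text: str) -> WeightedGraph:
    """Inverse of :func:`graph_to_json`."""
    obj = json.loads(text)
    n = int(obj["N"])
    w = np.zeros((n, n))
    for u, v, weight in obj["edges"]:
        w[int(u), int(v)] = float(weight)
        w[int(v), int(u)] = float(weight)
    return WeightedGraph(w)
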