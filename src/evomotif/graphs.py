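"""Undirected population graphs: validation, motif statistics, edge swaps.

A population is an unweighted, undirected simple graph: nodes are
individuals, edges the replacement pattern between neighbours.  Graphs are
held as :class:`networkx.Graph` objects with 0-based contiguous integer
node ids; edges are unordered pairs reported in ``(i, j)``, ``i < j``
canonical form.

The structural summary of a graph is organised by motif dimension
(the dK hierarchy):

* d = 0 — mean degree,
* d = 1 — degree distribution,
* d = 2 — joint degree matrix / mixing pattern (summarised by the degree
  assortativity ``r``),
* d = 3 — wedges and triangles (summarised by the global transitivity
  ``phi = 3 * triangles / wedges``).

Transitivity here is always the *global* ratio over all connected triples,
not the mean local clustering coefficient: the pair approximation in
:mod:`evomotif.theory` uses a single graph-level ``phi``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "SwapRejected",
    "EdgeTypeMismatch",
    "MotifProfile",
    "validate_graph",
    "count_motifs",
    "transitivity",
    "assortativity",
    "joint_degree_matrix",
    "double_edge_swap",
    "two_k_swap",
    "edge_type",
    "is_connected",
]


class SwapRejected(ValueError):
    """The proposed edge swap would create a self-loop or parallel edge.

    Callers running a rewiring chain should catch this and re-propose;
    a rejected-invalid proposal is not an annealing step.
    """


class EdgeTypeMismatch(ValueError):
    """A 2K-preserving swap was proposed between edges of unequal degree type."""


@dataclass(frozen=True)
class MotifProfile:
    """Motif summary of a graph: the 0K--3K structural profile.

    Attributes
    ----------
    n_nodes, n_edges : int
        Node and edge counts.
    wedges : int
        Number of paths of length two (open triples), counted once per
        centre node: ``sum_i C(k_i, 2)``.
    triangles : int
        Number of closed triples (each triangle counted once).
    transitivity : float
        Global transitivity ``phi = 3 * triangles / wedges``; ``nan`` when
        the graph has no wedges.
    assortativity : float
        Pearson correlation of the degrees at the two ends of an edge;
        ``nan`` for degree-regular graphs (zero degree variance on edges).
    joint_degrees : dict
        ``{(i, j): count}`` with ``i <= j`` — number of edges linking a
        degree-``i`` node to a degree-``j`` node.  Sums to ``n_edges``.
    """

    n_nodes: int
    n_edges: int
    wedges: int
    triangles: int
    transitivity: float
    assortativity: float
    joint_degrees: dict = field(default_factory=dict)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes


def validate_graph(g: nx.Graph, require_connected: bool = False) -> nx.Graph:
    """Check the population-graph invariants, returning ``g`` unchanged.

    Raises ``ValueError`` on an empty graph, self-loops, non-contiguous or
    non-integer node labels, and (when ``require_connected``) on a
    disconnected graph.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("no nodes")
    if nx.number_of_selfloops(g) > 0:
        raise ValueError("self-loops are not allowed in population graphs")
    if set(g.nodes) != set(range(n)):
        raise ValueError("node ids must be 0-based contiguous integers")
    if require_connected and not nx.is_connected(g):
        raise ValueError("graph is not connected")
    return g


def is_connected(g: nx.Graph) -> bool:
    """True iff a single traversal reaches every node."""
    if g.number_of_nodes() == 0:
        raise ValueError("no nodes")
    return nx.is_connected(g)


def transitivity(g: nx.Graph) -> float:
    """Global transitivity phi = 3 * triangles / wedges (nan if no wedges)."""
    wedges = sum(d * (d - 1) // 2 for _, d in g.degree)
    if wedges == 0:
        return math.nan
    tri = sum(nx.triangles(g).values()) // 3
    return 3.0 * tri / wedges


def assortativity(g: nx.Graph) -> float:
    """Degree assortativity: Pearson correlation of degrees across edges.

    Both orientations of every edge enter the correlation, so the result
    is symmetric.  Returns ``nan`` when the degree variance over edge
    endpoints is zero (e.g. any regular graph) — the coefficient is
    undefined there, and a sentinel is deliberately preferred over 0.
    """
    if g.number_of_edges() < 1:
        return math.nan
    deg = dict(g.degree)
    x = np.array([deg[u] for u, v in g.edges] + [deg[v] for u, v in g.edges], float)
    y = np.array([deg[v] for u, v in g.edges] + [deg[u] for u, v in g.edges], float)
    vx = x.var()
    if vx == 0.0:
        return math.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / vx)


def joint_degree_matrix(g: nx.Graph) -> dict:
    """Edge counts by unordered endpoint-degree pair: {(i, j), i<=j: count}."""
    deg = dict(g.degree)
    return dict(Counter(tuple(sorted((deg[u], deg[v]))) for u, v in g.edges))


def count_motifs(g: nx.Graph) -> MotifProfile:
    """Exact motif counts and mixing summary of a graph.

    Triangles come from per-node triangle counts (each triangle counted
    three times, once per corner); wedges from the degree sequence.
    """
    validate_graph(g)
    degs = [d for _, d in g.degree]
    wedges = sum(d * (d - 1) // 2 for d in degs)
    tri = sum(nx.triangles(g).values()) // 3
    phi = 3.0 * tri / wedges if wedges > 0 else math.nan
    return MotifProfile(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        wedges=wedges,
        triangles=tri,
        transitivity=phi,
        assortativity=assortativity(g),
        joint_degrees=joint_degree_matrix(g),
    )


def _as_edge(g: nx.Graph, e) -> tuple:
    u, v = e
    if not g.has_edge(u, v):
        raise ValueError(f"edge {e!r} not in graph")
    return u, v


def double_edge_swap(g: nx.Graph, edge1, edge2, orientation: str = "parallel") -> nx.Graph:
    """Degree-preserving swap of two disjoint edges; returns a new graph.

    Removing ``(a, b)`` and ``(c, d)``, orientation ``"parallel"`` adds
    ``(a, c), (b, d)``; ``"crossed"`` adds ``(a, d), (b, c)``.  Every
    node's degree and the edge count are unchanged by construction.

    Raises
    ------
    SwapRejected
        If the edges share an endpoint, or either replacement edge is
        already present (a self-loop can only arise via shared endpoints,
        which is the same rejection).
    """
    a, b = _as_edge(g, edge1)
    c, d = _as_edge(g, edge2)
    if orientation == "crossed":
        c, d = d, c
    elif orientation != "parallel":
        raise ValueError("orientation must be 'parallel' or 'crossed'")
    if len({a, b, c, d}) < 4:
        raise SwapRejected("edges share an endpoint")
    if g.has_edge(a, c) or g.has_edge(b, d):
        raise SwapRejected("swap would create a parallel edge")
    h = g.copy()
    h.remove_edge(a, b)
    h.remove_edge(c, d)
    h.add_edge(a, c)
    h.add_edge(b, d)
    return h


def edge_type(g: nx.Graph, e) -> tuple:
    """Unordered degree pair of an edge's endpoints — its 2K 'type'."""
    u, v = _as_edge(g, e)
    return tuple(sorted((g.degree(u), g.degree(v))))


def two_k_swap(g: nx.Graph, edge1, edge2) -> nx.Graph:
    """Joint-degree-preserving rewiring of two same-type edges.

    The generalisation of the degree-preserving swap one level up the dK
    hierarchy: both edges must have the same unordered endpoint-degree
    pair, and the replacement edges pair each low-degree end with the
    other edge's high-degree end, so the joint degree matrix (hence the
    degree distribution and the assortativity) is exactly conserved while
    the triangle count may change.

    Raises ``EdgeTypeMismatch`` for edges of unequal type and
    ``SwapRejected`` for shared endpoints / existing replacement edges.
    """
    a, b = _as_edge(g, edge1)
    c, d = _as_edge(g, edge2)
    if edge_type(g, edge1) != edge_type(g, edge2):
        raise EdgeTypeMismatch("type mismatch")
    # orient both edges identically by degree so the pairing below conserves J
    if g.degree(a) > g.degree(b):
        a, b = b, a
    if g.degree(c) > g.degree(d):
        c, d = d, c
    if len({a, b, c, d}) < 4:
        raise SwapRejected("edges share an endpoint")
    # new edges (a, d) and (c, b): each again joins a deg(a)-end to a deg(b)-end
    if g.has_edge(a, d) or g.has_edge(c, b):
        raise SwapRejected("swap would create a parallel edge")
    h = g.copy()
    h.remove_edge(a, b)
    h.remove_edge(c, d)
    h.add_edge(a, d)
    h.add_edge(c, b)
    return h
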