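"""Random-graph generation with annealed motif tuning.

Generators produce graphs with a prescribed degree structure and then
rewire them toward a target triangle fraction (and, for two-degree-class
graphs, a target assortativity) while holding the lower levels of the dK
hierarchy fixed:

* :func:`tune_transitivity_regular` — Metropolis--Hastings chain of
  degree-preserving double edge swaps with a Gaussian acceptance density
  centred on ``phi_target`` (variance ``sigma**2``); swaps toward the
  target are always accepted, swaps away are accepted with the MH ratio.
  ``sigma`` is *grown* by a small factor on a fixed cadence, relaxing the
  criterion as the chain proceeds.
* :func:`tune_assortativity` — the same annealed chain driving the degree
  correlation ``r`` instead of ``phi`` (degree distribution fixed, mixing
  pattern varied).
* :func:`tune_transitivity_2k` — joint-degree-preserving (2K) rewiring:
  only same-type edge pairs are swapped, so the joint degree matrix and
  the assortativity are conserved *exactly*; moves toward the target are
  always accepted, moves away with probability ``gamma`` (1/gamma is the
  annealing temperature, decayed on a schedule).

Every accepted swap is followed by a connectivity check; a swap that
disconnects the graph is reverted (and still consumes a proposal).
Proposals that would create self-loops or parallel edges are re-drawn
without consuming budget, which preserves the uniformity argument for the
underlying swap chain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graphs import validate_graph

__all__ = [
    "AnnealConfig",
    "DegreeClassSpec",
    "random_regular",
    "tune_transitivity_regular",
    "tune_transitivity_2k",
    "tune_assortativity",
    "build_two_class_graph",
    "tuned_regular_graph",
    "tuned_two_class_graph",
]


@dataclass
class AnnealConfig:
    """Schedule for the motif-tuning chains.

    Parameters
    ----------
    phi_target : float
        Target triangle fraction in [0, 1].
    sigma0 : float
        Initial width of the Gaussian acceptance density.  The printed
        schedule fixes only the growth; a tight start (0.005) makes the
        early phase effectively greedy.
    sigma_growth : float
        Multiplicative growth applied to sigma every ``sigma_interval``
        consumed proposals (default 1.001).
    sigma_interval : int, optional
        Cadence of sigma updates; defaults to ``N * k`` proposals.
    budget : int, optional
        Total number of consumed (valid) proposals; defaults to
        ``k * 1_000_000`` with ``k`` the mean degree, the full-scale run.
    gamma0, gamma_decay, gamma_interval :
        Temperature schedule for the 2K chain: away-from-target moves are
        accepted with probability ``gamma``; ``gamma`` starts at
        ``gamma0`` (0.5) and is multiplied by ``gamma_decay`` (0.99)
        every ``gamma_interval`` proposals (default ``N * mean_degree``).
    tol : float, optional
        Early-stop tolerance on ``|phi - phi_target|``; ``None`` runs the
        full budget (the chain then samples around the target).
    seed : int, optional
        Seed for the proposal stream.
    """

    phi_target: float = 0.0
    sigma0: float = 0.005
    sigma_growth: float = 1.001
    sigma_interval: int | None = None
    budget: int | None = None
    gamma0: float = 0.5
    gamma_decay: float = 0.99
    gamma_interval: int | None = None
    tol: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.phi_target <= 1.0:
            raise ValueError("phi_target must be in [0, 1]")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if not 0.0 < self.gamma0 <= 1.0:
            raise ValueError("gamma0 must be in (0, 1]")
        if self.budget is not None and self.budget < 1:
            raise ValueError("budget must be >= 1")


@dataclass
class DegreeClassSpec:
    """Two-degree-class graph specification: [(n1, k1), (n2, k2)].

    ``classes`` lists (group size, group degree) pairs; ``r_target`` is an
    optional assortativity to anneal toward after assembly.
    """

    classes: list
    r_target: float | None = None

    def __post_init__(self):
        if not self.classes:
            raise ValueError("at least one degree class required")
        n_total = sum(n for n, _ in self.classes)
        for n, k in self.classes:
            if n < 1 or k < 1:
                raise ValueError("class sizes and degrees must be positive")
            if k >= n_total:
                raise ValueError("class degree must be smaller than graph size")
        if sum(n * k for n, k in self.classes) % 2 != 0:
            raise ValueError("infeasible degree sequence: sum of degrees is odd")

    @property
    def n_nodes(self) -> int:
        return sum(n for n, _ in self.classes)

    @property
    def mean_degree(self) -> float:
        return sum(n * k for n, k in self.classes) / self.n_nodes


def random_regular(n: int, k: int, seed=None) -> nx.Graph:
    """Connected random k-regular graph on n nodes.

    Raises on an infeasible degree sequence (``n*k`` odd or ``k >= n``).
    Resamples until connected (for k >= 3 almost every sample already is).
    """
    if k >= n:
        raise ValueError("degree k must be smaller than n")
    if (n * k) % 2 != 0:
        raise ValueError("infeasible degree sequence: n*k is odd")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        g = nx.random_regular_graph(k, n, seed=int(rng.integers(2**31)))
        if k == 0 or nx.is_connected(g):
            return g
    raise RuntimeError("failed to sample a connected regular graph")


# ---------------------------------------------------------------------------
# internal mutable graph state with incremental motif deltas


class _SwapState:
    """Adjacency-set view of a graph with O(k) triangle-count updates."""

    __slots__ = ("n", "adj", "edges", "deg", "wedges", "tri", "s_jk")

    def __init__(self, g: nx.Graph):
        self.n = g.number_of_nodes()
        self.adj = [set(g[u]) for u in range(self.n)]
        self.edges = [list(e) for e in g.edges]
        self.deg = [len(a) for a in self.adj]
        self.wedges = sum(d * (d - 1) // 2 for d in self.deg)
        self.tri = sum(nx.triangles(g).values()) // 3
        # sum over edges of deg(u)*deg(v); drives the assortativity
        self.s_jk = sum(self.deg[u] * self.deg[v] for u, v in self.edges)

    # -- metrics ----------------------------------------------------------
    def phi(self) -> float:
        return 3.0 * self.tri / self.wedges if self.wedges else math.nan

    def assort_constants(self):
        """(mean, variance) of endpoint degrees over directed edges."""
        deg = self.deg
        tot = sum(deg[u] + deg[v] for u, v in self.edges)
        m = 2 * len(self.edges)
        mu = tot / m
        var = sum(deg[u] ** 2 + deg[v] ** 2 for u, v in self.edges) / m - mu * mu
        return mu, var

    def assortativity(self, mu: float, var: float) -> float:
        return (self.s_jk / len(self.edges) - mu * mu) / var

    # -- swap mechanics ---------------------------------------------------
    def swap_valid(self, a, b, c, d) -> bool:
        """Can edges (a,b),(c,d) be rewired to (a,c),(b,d)?"""
        if len({a, b, c, d}) < 4:
            return False
        return c not in self.adj[a] and d not in self.adj[b]

    def tri_delta(self, a, b, c, d) -> int:
        """Triangle-count change of rewiring (a,b),(c,d) -> (a,c),(b,d).

        Removed triangles sit on the removed edges (common neighbours of
        their endpoints); added ones on the new edges, counted in the
        graph with both old edges deleted.  The two new edges are
        node-disjoint, so no triangle contains both and the sum is exact.
        """
        A, B, C, D = self.adj[a], self.adj[b], self.adj[c], self.adj[d]
        removed = len(A & B) + len(C & D)
        added = len((A - {b}) & (C - {d})) + len((B - {a}) & (D - {c}))
        return added - removed

    def sjk_delta(self, a, b, c, d) -> int:
        deg = self.deg
        return (deg[a] * deg[c] + deg[b] * deg[d]) - (deg[a] * deg[b] + deg[c] * deg[d])

    def apply(self, i, j, a, b, c, d, d_tri):
        """Replace edge slots i -> (a,c) and j -> (b,d)."""
        self.adj[a].discard(b); self.adj[b].discard(a)
        self.adj[c].discard(d); self.adj[d].discard(c)
        self.adj[a].add(c); self.adj[c].add(a)
        self.adj[b].add(d); self.adj[d].add(b)
        self.edges[i] = [a, c]
        self.edges[j] = [b, d]
        self.tri += d_tri
        self.s_jk += self.sjk_delta_applied(a, b, c, d)

    def sjk_delta_applied(self, a, b, c, d) -> int:
        deg = self.deg
        return (deg[a] * deg[c] + deg[b] * deg[d]) - (deg[a] * deg[b] + deg[c] * deg[d])

    def connected(self) -> bool:
        n = self.n
        seen = bytearray(n)
        stack = [0]
        seen[0] = 1
        count = 1
        adj = self.adj
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = 1
                    count += 1
                    stack.append(v)
        return count == n

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from((u, v) for u, v in self.edges)
        return g


def _edges_snapshot(state: _SwapState):
    return [tuple(e) for e in state.edges]


def _restore(state_graph_nodes: int, edges) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(state_graph_nodes))
    g.add_edges_from(edges)
    return g


def _run_anneal(
    state: _SwapState,
    *,
    mode: str,  # "gaussian" or "gamma"
    two_k: bool,
    target: float,
    cfg: AnnealConfig,
    metric: str,  # "phi" or "assort"
    rng: np.random.Generator,
):
    """Drive the compiled annealing chain.  Returns (best_edges, best_err)."""
    from ._anneal import (
        METRIC_ASSORT,
        METRIC_PHI,
        MODE_GAMMA,
        MODE_GAUSSIAN,
        anneal_chain,
    )

    n_edges = len(state.edges)
    if n_edges < 2:
        raise ValueError("need at least 2 edges to swap")

    if metric == "assort":
        mu, var = state.assort_constants()
        if var <= 0:
            raise ValueError("assortativity undefined for regular graphs")
    else:
        mu, var = 0.0, 1.0

    n = state.n
    deg = np.array(state.deg, np.int64)
    kmax = int(deg.max())
    nbr = np.full((n, kmax), -1, np.int64)
    fill = np.zeros(n, np.int64)
    adjm = np.zeros((n, n), np.bool_)
    for u, v in state.edges:
        nbr[u, fill[u]] = v
        fill[u] += 1
        nbr[v, fill[v]] = u
        fill[v] += 1
        adjm[u, v] = adjm[v, u] = True
    edges = np.array(state.edges, np.int64)

    # 2K proposals draw the partner edge from a same-degree-type bucket;
    # the type of every edge slot is invariant under 2K swaps, so the
    # buckets are built once.
    if two_k:
        keys = [tuple(sorted((state.deg[u], state.deg[v]))) for u, v in state.edges]
        uniq = sorted(set(keys))
        key_id = {key: t for t, key in enumerate(uniq)}
        etype = np.array([key_id[key] for key in keys], np.int64)
        order = np.argsort(etype, kind="stable")
        bucket_items = order.astype(np.int64)
        bucket_start = np.zeros(len(uniq) + 1, np.int64)
        for t in etype:
            bucket_start[t + 1] += 1
        bucket_start = np.cumsum(bucket_start)
        counts = np.bincount(etype)
        if not (counts >= 2).any():
            raise ValueError("2K swap infeasible: no same-type edge pair exists")
    else:
        etype = np.zeros(n_edges, np.int64)
        bucket_items = np.arange(n_edges, dtype=np.int64)
        bucket_start = np.array([0, n_edges], np.int64)

    kbar = 2.0 * n_edges / n
    budget = cfg.budget if cfg.budget is not None else int(round(kbar)) * 1_000_000
    interval = cfg.sigma_interval or max(1, int(n * kbar))
    g_interval = cfg.gamma_interval or max(1, int(n * kbar))

    best_edges = np.empty_like(edges)
    best_err, _consumed, _best_tri = anneal_chain(
        nbr, deg, adjm, edges,
        state.tri, state.wedges, float(state.s_jk), mu, var,
        METRIC_PHI if metric == "phi" else METRIC_ASSORT,
        MODE_GAUSSIAN if mode == "gaussian" else MODE_GAMMA,
        two_k,
        etype, bucket_start, bucket_items,
        float(target), cfg.sigma0, cfg.sigma_growth, interval,
        cfg.gamma0, cfg.gamma_decay, g_interval,
        int(budget),
        0.0 if cfg.tol is None else float(cfg.tol), cfg.tol is not None,
        int(rng.integers(1, 2**31)),
        best_edges,
    )
    return [tuple(e) for e in best_edges.tolist()], float(best_err)


def _finish(state: _SwapState, best_edges, best_err, target, cfg, what: str) -> nx.Graph:
    g = _restore(state.n, best_edges)
    tol = cfg.tol if cfg.tol is not None else 0.02
    converged = best_err <= tol
    g.graph.update(
        {f"{what}_target": target, f"{what}_error": best_err, "converged": bool(converged)}
    )
    if not converged:
        warnings.warn(
            f"annealing stopped {best_err:.4f} away from the {what} target {target}; "
            "returning best-found graph",
            stacklevel=3,
        )
    return g


def tune_transitivity_regular(graph: nx.Graph, cfg: AnnealConfig) -> nx.Graph:
    """Anneal a regular graph's triangle fraction toward ``cfg.phi_target``.

    Degree-preserving double edge swaps accepted by the Metropolis--
    Hastings ratio of Gaussian densities centred on the target; the
    degree sequence is conserved exactly and the returned graph is
    connected.  If the target is unreachable within the budget the
    best-found graph is returned with ``graph['converged'] = False`` and
    a warning.
    """
    validate_graph(graph, require_connected=True)
    degs = {d for _, d in graph.degree}
    if len(degs) != 1:
        raise ValueError("tune_transitivity_regular requires a regular graph")
    state = _SwapState(graph)
    rng = np.random.default_rng(cfg.seed)
    best_edges, best_err = _run_anneal(
        state, mode="gaussian", two_k=False, target=cfg.phi_target, cfg=cfg,
        metric="phi", rng=rng,
    )
    return _finish(state, best_edges, best_err, cfg.phi_target, cfg, "phi")


def tune_transitivity_2k(graph: nx.Graph, cfg: AnnealConfig) -> nx.Graph:
    """Anneal the triangle fraction with 2K-preserving rewiring.

    Only same-degree-type edge pairs are swapped, so the joint degree
    matrix — and with it the degree distribution and the assortativity —
    is conserved exactly.  Moves toward the target are always accepted;
    moves away with probability ``gamma`` (decayed on its schedule).
    """
    validate_graph(graph, require_connected=True)
    state = _SwapState(graph)
    rng = np.random.default_rng(cfg.seed)
    best_edges, best_err = _run_anneal(
        state, mode="gamma", two_k=True, target=cfg.phi_target, cfg=cfg,
        metric="phi", rng=rng,
    )
    return _finish(state, best_edges, best_err, cfg.phi_target, cfg, "phi")


def tune_assortativity(graph: nx.Graph, r_target: float, cfg: AnnealConfig | None = None) -> nx.Graph:
    """Anneal the degree assortativity toward ``r_target``.

    Degree-preserving double edge swaps with the Gaussian MH criterion
    applied to ``r``; the degree sequence is exact, connectivity is
    enforced.  Raises for regular input graphs, where ``r`` is undefined.
    """
    validate_graph(graph, require_connected=True)
    cfg = cfg or AnnealConfig(budget=100_000, tol=0.02)
    state = _SwapState(graph)
    rng = np.random.default_rng(cfg.seed)
    best_edges, best_err = _run_anneal(
        state, mode="gaussian", two_k=False, target=r_target, cfg=cfg,
        metric="assort", rng=rng,
    )
    return _finish(state, best_edges, best_err, r_target, cfg, "assortativity")


def build_two_class_graph(spec: DegreeClassSpec, seed=None, mix_swaps: int | None = None) -> nx.Graph:
    """Connected graph with two prescribed degree classes.

    Starts from independent random regular graphs, one per class, then
    applies random degree-preserving swaps to wire the classes together
    (each cross-class swap creates cross edges while conserving every
    node's degree), continuing until the union is connected.  If
    ``spec.r_target`` is set, the mixing pattern is then annealed toward
    that assortativity.
    """
    rng = np.random.default_rng(seed)
    classes = list(spec.classes)
    if len({k for _, k in classes}) == 1:
        # degenerate: identical degrees reduce to a single regular graph
        return random_regular(spec.n_nodes, classes[0][1], seed=rng)
    if len(classes) != 2:
        raise ValueError("exactly two degree classes are supported")

    (n1, k1), (n2, k2) = classes
    g1 = random_regular(n1, k1, seed=rng)
    g2 = nx.relabel_nodes(random_regular(n2, k2, seed=rng), {i: i + n1 for i in range(n2)})
    g = nx.Graph()
    g.add_nodes_from(range(n1 + n2))
    g.add_edges_from(g1.edges)
    g.add_edges_from(g2.edges)

    state = _SwapState(g)
    n_edges = len(state.edges)
    target_swaps = mix_swaps if mix_swaps is not None else 2 * n_edges
    done = 0
    guard = 0
    # randomise mixing; connectivity only demanded of the final graph
    while done < target_swaps or not state.connected():
        guard += 1
        if guard > 100 * target_swaps + 100_000:
            raise RuntimeError("failed to connect the two degree classes")
        i = int(rng.integers(n_edges))
        j = int(rng.integers(n_edges))
        if i == j:
            continue
        u1, v1 = state.edges[i]
        u2, v2 = state.edges[j]
        if rng.integers(2):
            u2, v2 = v2, u2
        if not state.swap_valid(u1, v1, u2, v2):
            continue
        d_tri = state.tri_delta(u1, v1, u2, v2)
        state.apply(i, j, u1, v1, u2, v2, d_tri)
        done += 1

    out = state.to_graph()
    if spec.r_target is not None:
        out = tune_assortativity(out, spec.r_target, AnnealConfig(budget=100_000, tol=0.02, seed=int(rng.integers(2**31))))
    return out


def tuned_regular_graph(n: int, k: int, phi_target: float, *, budget: int | None = None,
                        tol: float | None = 0.01, seed=None) -> nx.Graph:
    """Convenience pipeline: random regular graph annealed to ``phi_target``."""
    rng = np.random.default_rng(seed)
    g = random_regular(n, k, seed=rng)
    cfg = AnnealConfig(phi_target=phi_target, budget=budget, tol=tol,
                       seed=int(rng.integers(2**31)))
    return tune_transitivity_regular(g, cfg)


def tuned_two_class_graph(spec: DegreeClassSpec, phi_target: float, *,
                          budget: int | None = None, tol: float | None = 0.01,
                          seed=None) -> nx.Graph:
    """Two-class graph with annealed assortativity, then 2K-tuned transitivity."""
    rng = np.random.default_rng(seed)
    g = build_two_class_graph(spec, seed=rng)
    cfg = AnnealConfig(phi_target=phi_target, budget=budget, tol=tol,
                       seed=int(rng.integers(2**31)))
    return tune_transitivity_2k(g, cfg)
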