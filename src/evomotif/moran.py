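"""Moran Birth-death / death-Birth dynamics on graphs.

Exact stochastic simulation of a single mutant lineage invading a
graph-structured resident population, Monte Carlo estimation of the
fixation probability and the conditional fixation time, trajectory
recording of node and edge frequencies, and a brute-force solver over the
full 2^N configuration space for small graphs, used as a testing oracle.

Conventions
-----------
* Mutants (allele ``a``) have fitness ``1 + s``; residents (``A``) have
  fitness 1.  Population size is fixed.
* One *event* is one replacement step.  A *generation* is N events.
* ``Bd``: the reproducer is drawn fitness-proportionally from the whole
  population, then a uniformly random neighbour dies.  ``dB``: a
  uniformly random individual dies, then the neighbours of the vacancy
  compete fitness-proportionally to refill it.
* Edge-type frequencies use the ordered edge-end convention,
  ``p_Aa = (# mixed edges) / (2E)``, under which the bookkeeping
  identities ``p_AA = (1 - p_a) - p_Aa`` and ``p_aa = p_a - p_Aa`` hold
  exactly on regular graphs (where the node frequency equals the
  edge-end frequency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from .graphs import validate_graph

__all__ = [
    "MoranConfig",
    "FixationEstimate",
    "TrajectoryRecord",
    "EnsembleTrajectory",
    "SmallGraphSolution",
    "graph_to_csr",
    "run_to_absorption",
    "estimate_fixation",
    "record_mean_trajectories",
    "exact_small_graph_solve",
]

_RULES = {"Bd": 0, "dB": 1}


@dataclass
class MoranConfig:
    """Parameters of one Moran simulation.

    ``init`` selects the initial condition: ``"random"`` places a single
    mutant on a uniformly random node per replicate; an explicit iterable
    of node ids seeds exactly those nodes; a float in (0, 1) seeds
    ``round(p * N)`` uniformly chosen nodes.
    """

    s: float = 0.0
    rule: str = "Bd"
    init: object = "random"
    max_events: int = 100_000_000
    seed: int | None = None
    record: bool = False
    cadence: int | None = None  # record every `cadence` events; default N

    def __post_init__(self):
        if 1.0 + self.s <= 0.0:
            raise ValueError("mutant fitness 1+s must be positive")
        if self.rule not in _RULES:
            raise ValueError("rule must be 'Bd' or 'dB'")
        if self.max_events <= 0:
            raise ValueError("max_events must be positive")


@dataclass
class TrajectoryRecord:
    """Recorded frequency trajectory of a single replicate."""

    times: np.ndarray          # events at each record point
    p_a: np.ndarray            # mutant node frequency
    p_Aa: np.ndarray           # mixed-edge frequency, ordered convention
    outcome: str               # "fixed" | "lost" | "censored"

    @property
    def p_AA(self) -> np.ndarray:
        return (1.0 - self.p_a) - self.p_Aa

    @property
    def p_aa(self) -> np.ndarray:
        return self.p_a - self.p_Aa


@dataclass
class FixationEstimate:
    """Monte Carlo fixation estimate with binomial standard error.

    ``se`` is sqrt(P_MC (1 - P_MC) / n_MC) — the square root of the
    Bernoulli sampling variance of the probability estimate.  The
    conditional fixation time averages the fixing replicates only and is
    ``nan`` when none fixed; censored replicates are counted separately
    and never folded into either absorbing outcome.
    """

    n_replicates: int
    n_fixed: int
    n_lost: int
    n_censored: int
    probability: float
    se: float
    cond_time_events: float
    cond_time_se_events: float
    n_nodes: int

    @property
    def usable(self) -> bool:
        return self.n_censored < self.n_replicates

    @property
    def cond_time_generations(self) -> float:
        return self.cond_time_events / self.n_nodes

    @property
    def cond_time_se_generations(self) -> float:
        return self.cond_time_se_events / self.n_nodes


@dataclass
class EnsembleTrajectory:
    """Per-time-point ensemble means over (optionally fixation-conditioned) runs."""

    times: np.ndarray
    mean_p_a: np.ndarray
    mean_p_Aa: np.ndarray
    n_runs: np.ndarray          # replicates contributing at each time point
    ratio: np.ndarray           # mean of p_Aa / (p_A p_a) at each time point
    plateau_ratio: float        # mean ratio over points with p_a in the band
    plateau_se: float
    band: tuple
    n_fixed: int
    n_total: int

    @property
    def mean_p_AA(self) -> np.ndarray:
        return (1.0 - self.mean_p_a) - self.mean_p_Aa

    @property
    def mean_p_aa(self) -> np.ndarray:
        return self.mean_p_a - self.mean_p_Aa


def graph_to_csr(g: nx.Graph):
    """Adjacency of a validated graph in CSR form (indptr, indices)."""
    validate_graph(g)
    n = g.number_of_nodes()
    indptr = np.zeros(n + 1, dtype=np.int64)
    for v in range(n):
        indptr[v + 1] = indptr[v] + g.degree(v)
    indices = np.empty(indptr[-1], dtype=np.int64)
    fill = indptr[:-1].copy()
    for u, v in g.edges:
        indices[fill[u]] = v
        fill[u] += 1
        indices[fill[v]] = u
        fill[v] += 1
    return indptr, indices


@njit(cache=True)
def _sim(indptr, indices, types, s, rule, max_events, seed, cadence, rec_pa, rec_paa):
    """One replicate to absorption (or the event cap).

    Mutates ``types`` in place; returns (outcome, events, n_recorded,
    mixed_edge_count) with outcome 1=fixed, 0=lost, 2=censored.  The
    mixed-edge count is maintained incrementally by scanning only the
    replaced node's neighbourhood (O(degree) per event) and is returned
    so callers can audit it against a from-scratch recount.
    """
    np.random.seed(seed)
    n = indptr.shape[0] - 1
    two_e = indices.shape[0]

    # mutants occupy slots [0, m) of perm; pos is the inverse map
    perm = np.empty(n, np.int64)
    pos = np.empty(n, np.int64)
    m = 0
    for v in range(n):
        if types[v] == 1:
            perm[m] = v
            pos[v] = m
            m += 1
    w = m
    for v in range(n):
        if types[v] == 0:
            perm[w] = v
            pos[v] = w
            w += 1

    mixed = 0
    for v in range(n):
        for e in range(indptr[v], indptr[v + 1]):
            u = indices[e]
            if u > v and types[u] != types[v]:
                mixed += 1

    rec = rec_pa.shape[0] > 0
    nrec = 0
    if rec:
        rec_pa[0] = m / n
        rec_paa[0] = mixed / two_e
        nrec = 1

    events = 0
    while 0 < m < n and events < max_events:
        events += 1
        if rule == 0:  # Birth-death
            tot = (n - m) + (1.0 + s) * m
            if np.random.random() * tot < (1.0 + s) * m:
                repro = perm[int(np.random.random() * m)]
            else:
                repro = perm[m + int(np.random.random() * (n - m))]
            lo = indptr[repro]
            hi = indptr[repro + 1]
            victim = indices[lo + int(np.random.random() * (hi - lo))]
            newt = types[repro]
        else:  # death-Birth
            victim = int(np.random.random() * n)
            lo = indptr[victim]
            hi = indptr[victim + 1]
            wsum = 0.0
            for e in range(lo, hi):
                if types[indices[e]] == 1:
                    wsum += 1.0 + s
                else:
                    wsum += 1.0
            u = np.random.random() * wsum
            parent = indices[hi - 1]
            acc = 0.0
            for e in range(lo, hi):
                if types[indices[e]] == 1:
                    acc += 1.0 + s
                else:
                    acc += 1.0
                if u < acc:
                    parent = indices[e]
                    break
            newt = types[parent]

        if types[victim] != newt:
            for e in range(indptr[victim], indptr[victim + 1]):
                if types[indices[e]] == newt:
                    mixed -= 1
                else:
                    mixed += 1
            j = pos[victim]
            if newt == 1:
                other = perm[m]
                perm[m] = victim
                pos[victim] = m
                perm[j] = other
                pos[other] = j
                m += 1
            else:
                last = m - 1
                other = perm[last]
                perm[last] = victim
                pos[victim] = last
                perm[j] = other
                pos[other] = j
                m -= 1
            types[victim] = newt

        if rec and events % cadence == 0 and nrec < rec_pa.shape[0]:
            rec_pa[nrec] = m / n
            rec_paa[nrec] = mixed / two_e
            nrec += 1

    if m == n:
        outcome = 1
    elif m == 0:
        outcome = 0
    else:
        outcome = 2
    return outcome, events, nrec, mixed


_OUTCOMES = {0: "lost", 1: "fixed", 2: "censored"}


def _initial_types(n: int, init, rng) -> np.ndarray:
    types = np.zeros(n, dtype=np.int8)
    if isinstance(init, str) and init == "random":
        types[rng.integers(n)] = 1
    elif isinstance(init, float):
        if not 0.0 <= init <= 1.0:
            raise ValueError("initial frequency must be in [0, 1]")
        k = int(round(init * n))
        types[rng.choice(n, size=k, replace=False)] = 1
    else:
        for v in init:
            types[v] = 1
    return types


def _kernel_seed(rng) -> int:
    return int(rng.integers(1, 2**31))


def run_to_absorption(graph: nx.Graph, cfg: MoranConfig, seed=None):
    """Run one replicate; returns (outcome, events, trajectory-or-None).

    ``outcome`` is ``"fixed"``, ``"lost"`` or ``"censored"`` (event cap
    hit before absorption).  The trajectory is recorded at ``cfg.cadence``
    events (default N) when ``cfg.record``.
    """
    validate_graph(graph, require_connected=True)
    indptr, indices = graph_to_csr(graph)
    n = graph.number_of_nodes()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    types = _initial_types(n, cfg.init, rng)
    cadence = cfg.cadence or n
    if cfg.record:
        cap = min(cfg.max_events // cadence + 1, 2_000_000)
        rec_pa = np.empty(cap)
        rec_paa = np.empty(cap)
    else:
        rec_pa = np.empty(0)
        rec_paa = np.empty(0)
    out, events, nrec, _ = _sim(
        indptr, indices, types, float(cfg.s), _RULES[cfg.rule],
        cfg.max_events, _kernel_seed(rng), cadence, rec_pa, rec_paa,
    )
    traj = None
    if cfg.record:
        traj = TrajectoryRecord(
            times=np.arange(nrec) * cadence,
            p_a=rec_pa[:nrec].copy(),
            p_Aa=rec_paa[:nrec].copy(),
            outcome=_OUTCOMES[out],
        )
    return _OUTCOMES[out], events, traj


def estimate_fixation(graph: nx.Graph, cfg: MoranConfig, n_mc: int, seed=None) -> FixationEstimate:
    """Monte Carlo fixation probability and conditional fixation time.

    Runs ``n_mc`` independent replicates (seeds split deterministically
    from the master seed), aggregates the fixation indicator with its
    binomial standard error and the mean absorption time of the fixing
    replicates with its sampling standard error.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    validate_graph(graph, require_connected=True)
    indptr, indices = graph_to_csr(graph)
    n = graph.number_of_nodes()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    empty = np.empty(0)
    n_fixed = n_lost = n_censored = 0
    fix_times = []
    rule = _RULES[cfg.rule]
    s = float(cfg.s)
    for _ in range(n_mc):
        types = _initial_types(n, cfg.init, rng)
        out, events, _, _ = _sim(
            indptr, indices, types, s, rule, cfg.max_events,
            _kernel_seed(rng), n, empty, empty,
        )
        if out == 1:
            n_fixed += 1
            fix_times.append(events)
        elif out == 0:
            n_lost += 1
        else:
            n_censored += 1
    n_done = n_fixed + n_lost  # censored runs carry no absorption outcome
    p = n_fixed / n_mc
    se = math.sqrt(p * (1.0 - p) / n_mc)
    if n_fixed > 0:
        ft = np.asarray(fix_times, float)
        t_mean = float(ft.mean())
        t_se = float(ft.std(ddof=1) / math.sqrt(n_fixed)) if n_fixed > 1 else math.nan
    else:
        t_mean = math.nan
        t_se = math.nan
    return FixationEstimate(
        n_replicates=n_mc,
        n_fixed=n_fixed,
        n_lost=n_lost,
        n_censored=n_censored,
        probability=p,
        se=se,
        cond_time_events=t_mean,
        cond_time_se_events=t_se,
        n_nodes=n,
    )


def record_mean_trajectories(
    graph: nx.Graph,
    cfg: MoranConfig,
    n_mc: int,
    condition_on_fixation: bool = True,
    ratio_band: tuple = (0.3, 0.7),
    seed=None,
) -> EnsembleTrajectory:
    """Ensemble-mean frequency trajectories, aligned at the first event.

    Averages ``p_a`` and ``p_Aa`` per time point over the contributing
    replicates (those that fixed, when ``condition_on_fixation``), and the
    ratio ``p_Aa / (p_A p_a)``, whose mid-sweep plateau estimates the
    pair-approximation constant ``1 - F``.  ``plateau_ratio`` averages the
    ratio over all recorded points with ``p_a`` inside ``ratio_band``.
    """
    validate_graph(graph, require_connected=True)
    indptr, indices = graph_to_csr(graph)
    n = graph.number_of_nodes()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    cadence = cfg.cadence or n
    cap = min(cfg.max_events // cadence + 1, 2_000_000)
    rec_pa = np.empty(cap)
    rec_paa = np.empty(cap)
    sum_pa = np.zeros(cap)
    sum_paa = np.zeros(cap)
    sum_ratio = np.zeros(cap)
    n_at = np.zeros(cap, dtype=np.int64)
    n_ratio_at = np.zeros(cap, dtype=np.int64)
    band_vals = []
    lo, hi = ratio_band
    n_fixed = 0
    max_len = 0
    rule = _RULES[cfg.rule]
    for _ in range(n_mc):
        types = _initial_types(n, cfg.init, rng)
        out, _, nrec, _ = _sim(
            indptr, indices, types, float(cfg.s), rule, cfg.max_events,
            _kernel_seed(rng), cadence, rec_pa, rec_paa,
        )
        if condition_on_fixation and out != 1:
            continue
        if out == 1:
            n_fixed += 1
        pa = rec_pa[:nrec]
        paa = rec_paa[:nrec]
        sum_pa[:nrec] += pa
        sum_paa[:nrec] += paa
        n_at[:nrec] += 1
        interior = (pa > 0.0) & (pa < 1.0)
        ratio = np.zeros(nrec)
        ratio[interior] = paa[interior] / (pa[interior] * (1.0 - pa[interior]))
        sum_ratio[:nrec][interior] += ratio[interior]
        n_ratio_at[:nrec][interior] += 1
        in_band = (pa >= lo) & (pa <= hi)
        if in_band.any():
            band_vals.append(ratio[in_band])
        max_len = max(max_len, nrec)

    used = n_at[:max_len] > 0
    times = (np.arange(max_len) * cadence)[used]
    mean_pa = sum_pa[:max_len][used] / n_at[:max_len][used]
    mean_paa = sum_paa[:max_len][used] / n_at[:max_len][used]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_ratio = np.where(
            n_ratio_at[:max_len][used] > 0,
            sum_ratio[:max_len][used] / np.maximum(n_ratio_at[:max_len][used], 1),
            np.nan,
        )
    if band_vals:
        flat = np.concatenate(band_vals)
        plateau = float(flat.mean())
        # conservative error: treat each contributing replicate's band mean
        # as one observation
        per_run = np.array([v.mean() for v in band_vals])
        plateau_se = float(per_run.std(ddof=1) / math.sqrt(len(per_run))) if len(per_run) > 1 else math.nan
    else:
        plateau = math.nan
        plateau_se = math.nan
    return EnsembleTrajectory(
        times=times,
        mean_p_a=mean_pa,
        mean_p_Aa=mean_paa,
        n_runs=n_at[:max_len][used],
        ratio=mean_ratio,
        plateau_ratio=plateau,
        plateau_se=plateau_se,
        band=ratio_band,
        n_fixed=n_fixed,
        n_total=n_mc,
    )


# ---------------------------------------------------------------------------
# exact configuration-space solver (testing oracle)


@dataclass
class SmallGraphSolution:
    """Exact fixation statistics from the 2^N configuration chain."""

    prob_per_node: np.ndarray        # fixation probability, single mutant at node i
    cond_time_per_node: np.ndarray   # conditional time in events, start at node i
    probability: float               # uniform-random single-mutant start
    cond_time_events: float          # uniform start, conditioned on fixation


def exact_small_graph_solve(graph: nx.Graph, s: float, rule: str = "Bd") -> SmallGraphSolution:
    """Solve the full configuration chain of the Moran process exactly.

    Builds the 2^N-state transition matrix (self-loops included, so times
    are in events), solves the absorbing-chain system for the fixation
    probability h and the h-transformed system for the conditional mean
    fixation time, exactly up to linear-solver tolerance.  Limited to
    N <= 14.
    """
    validate_graph(graph, require_connected=True)
    if rule not in _RULES:
        raise ValueError("rule must be 'Bd' or 'dB'")
    n = graph.number_of_nodes()
    if n > 14:
        raise ValueError("state space too big (N > 14)")
    nbrs = [list(graph[v]) for v in range(n)]
    deg = [len(a) for a in nbrs]
    nstates = 1 << n
    full = nstates - 1
    rows, cols, vals = [], [], []
    b = np.zeros(nstates - 2)

    def add(state, target, p):
        if target == full:
            b[state - 1] += p
        elif target != 0:
            rows.append(state - 1)
            cols.append(target - 1)
            vals.append(p)

    for state in range(1, nstates - 1):
        m = state.bit_count()
        if rule == "Bd":
            tot = n + s * m
            for i in range(n):
                fi = (1.0 + s) if (state >> i) & 1 else 1.0
                pi = fi / tot / deg[i]
                bit_i = (state >> i) & 1
                for j in nbrs[i]:
                    target = (state | (1 << j)) if bit_i else (state & ~(1 << j))
                    add(state, target, pi)
        else:  # dB
            for j in range(n):  # node chosen to die
                wsum = 0.0
                for i in nbrs[j]:
                    wsum += (1.0 + s) if (state >> i) & 1 else 1.0
                for i in nbrs[j]:
                    fi = (1.0 + s) if (state >> i) & 1 else 1.0
                    p = fi / wsum / n
                    bit_i = (state >> i) & 1
                    target = (state | (1 << j)) if bit_i else (state & ~(1 << j))
                    add(state, target, p)

    size = nstates - 2
    q = csr_matrix((vals, (rows, cols)), shape=(size, size))
    from scipy.sparse import identity

    a_mat = (identity(size, format="csr") - q).tocsc()
    h = spsolve(a_mat, b)
    u = spsolve(a_mat, h)

    prob = np.empty(n)
    tcond = np.empty(n)
    for i in range(n):
        idx = (1 << i) - 1
        prob[i] = h[idx]
        tcond[i] = u[idx] / h[idx] if h[idx] > 0 else math.nan
    h1 = np.array([h[(1 << i) - 1] for i in range(n)])
    u1 = np.array([u[(1 << i) - 1] for i in range(n)])
    return SmallGraphSolution(
        prob_per_node=prob,
        cond_time_per_node=tcond,
        probability=float(h1.mean()),
        cond_time_events=float(u1.mean() / h1.mean()),
    )
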