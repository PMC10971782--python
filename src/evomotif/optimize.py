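"""Evolutionary optimization on population graphs with rank selection.

Each node carries a real-valued genotype vector mapped to an objective
value; fitness is the population *rank* of that value, linear from
``1 + s`` (best) down to ``1 - s`` (worst), so the selection pressure is
constant regardless of the objective's scale.  The population evolves
under the Birth-death rule: the reproducer is drawn fitness-
proportionally from the whole population, a uniformly random neighbour is
replaced by its offspring, and on every reproduction either the parent or
the offspring (fair coin) receives an additive Gaussian mutation.

Two benchmark landscapes:

* smooth concave quadratic, ``1 - ||x - x*||^2`` (maximum value 1), and
* the inverted Rastrigin function, ``-(A d + sum_i (x_i^2 -
  A cos 2 pi x_i))`` with A = 10 (global maximum 0 at the origin, a
  lattice of local optima elsewhere).

The tracked summary is the mean population objective value on a fixed
recording cadence, and the time (in events) to first reach a threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from numba import njit

from .graphs import validate_graph
from .moran import graph_to_csr

__all__ = [
    "OptProblem",
    "OptTrajectory",
    "rank_fitness",
    "quadratic_objective",
    "rastrigin_objective",
    "evolve_on_graph",
    "time_to_threshold",
    "mean_time_to_threshold",
]

_OBJ = {"quadratic": 0, "rastrigin": 1}
_DEFAULT_SIGMA = {"quadratic": 0.012, "rastrigin": 0.12}


@dataclass
class OptProblem:
    """An optimization experiment's landscape and mutation/selection scales.

    Defaults reproduce the study conditions: 2-D genotypes, selection
    strength s = 1 (so the best individual has fitness 2 and the worst
    0), mutation standard deviation 0.012 on the quadratic landscape and
    0.12 on Rastrigin, threshold 0.95 for the quadratic time-to-target.
    The whole population starts at a common genotype: distance 1 from the
    quadratic optimum, and the (2, 2) local optimum for Rastrigin.
    """

    objective: str = "quadratic"
    dim: int = 2
    sigma: float | None = None
    s: float = 1.0
    theta: float | None = None
    start: np.ndarray | None = None
    bounds: tuple = (-5.12, 5.12)

    def __post_init__(self):
        if self.objective not in _OBJ:
            raise ValueError("objective must be 'quadratic' or 'rastrigin'")
        if self.sigma is None:
            self.sigma = _DEFAULT_SIGMA[self.objective]
        if self.sigma <= 0:
            raise ValueError("mutation scale must be positive")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("rank selection requires 0 <= s <= 1 (s=1 gives worst fitness 0)")
        if self.theta is None and self.objective == "quadratic":
            self.theta = 0.95
        if self.start is None:
            if self.objective == "quadratic":
                start = np.zeros(self.dim)
                start[0] = 1.0  # distance 1 from the optimum at the origin
            else:
                start = np.full(self.dim, 2.0)  # a local optimum of inverted Rastrigin
            self.start = start
        else:
            self.start = np.asarray(self.start, float)
            if self.start.shape != (self.dim,):
                raise ValueError("start genotype has wrong dimension")
        if self.theta is not None:
            top = 1.0 if self.objective == "quadratic" else 0.0
            if self.theta > top:
                raise ValueError("threshold above the objective's global maximum")


@dataclass
class OptTrajectory:
    """Recorded mean-population-value trajectory of one replicate."""

    replicate: int
    times: np.ndarray        # events, on the recording cadence
    mean_values: np.ndarray
    time_to_threshold: int | None   # events, None when censored
    censored: bool
    theta: float | None


def quadratic_objective(x, optimum=None) -> float:
    """Concave quadratic, global maximum 1 at ``optimum`` (default origin)."""
    x = np.asarray(x, float)
    if optimum is not None:
        x = x - np.asarray(optimum, float)
    return 1.0 - float(np.dot(x, x))


def rastrigin_objective(x) -> float:
    """Inverted Rastrigin (A = 10): global maximum 0 at the origin, <= 0 everywhere."""
    x = np.asarray(x, float)
    a = 10.0
    return -float(a * x.size + np.sum(x * x - a * np.cos(2.0 * math.pi * x)))


def rank_fitness(values, s: float, rng=None) -> np.ndarray:
    """Linear rank-selection fitness map.

    The highest objective value gets fitness ``1 + s``, decreasing
    linearly to ``1 - s`` for the lowest; ties are broken by a uniformly
    random permutation among the tied individuals.  The mean fitness is
    exactly 1 at every call.  ``s`` must satisfy ``0 <= s <= 1`` (s = 1
    assigns the worst individual fitness 0, the strongest admissible
    pressure).
    """
    values = np.asarray(values, float)
    n = values.size
    if n < 2:
        raise ValueError("rank selection needs at least 2 individuals")
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must be in [0, 1]")
    rng = np.random.default_rng(rng)
    shuffle = rng.permutation(n)
    order = shuffle[np.argsort(values[shuffle], kind="stable")]  # ascending; ties random
    fitness = np.empty(n)
    ranks_from_worst = np.arange(n, dtype=float)
    fitness[order] = (1.0 - s) + 2.0 * s * ranks_from_worst / (n - 1)
    return fitness


@njit(cache=True)
def _objective_value(obj_id, g, n_dim):
    if obj_id == 0:
        acc = 0.0
        for i in range(n_dim):
            acc += g[i] * g[i]
        return 1.0 - acc
    acc = 10.0 * n_dim
    for i in range(n_dim):
        acc += g[i] * g[i] - 10.0 * math.cos(2.0 * math.pi * g[i])
    return -acc


@njit(cache=True)
def _reposition(sorted_nodes, rank_of, vals, node):
    """Restore sort order after ``vals[node]`` changed (insertion move)."""
    n = sorted_nodes.shape[0]
    r = rank_of[node]
    v = vals[node]
    while r + 1 < n and vals[sorted_nodes[r + 1]] < v:
        other = sorted_nodes[r + 1]
        sorted_nodes[r] = other
        rank_of[other] = r
        r += 1
        sorted_nodes[r] = node
    while r > 0 and vals[sorted_nodes[r - 1]] > v:
        other = sorted_nodes[r - 1]
        sorted_nodes[r] = other
        rank_of[other] = r
        r -= 1
        sorted_nodes[r] = node
    rank_of[node] = r


@njit(cache=True)
def _evolve(indptr, indices, s, obj_id, sigma, start, cadence, max_events, theta,
            stop_at_theta, seed, rec):
    """One optimization replicate; returns (n_recorded, t_hit).

    Every event: draw a reproducer rank from the (static) linear rank-
    fitness distribution, map it to a node through an incrementally
    maintained sort order (so ranks are exact at every event), replace a
    uniform neighbour, then mutate parent or offspring with equal
    probability.  The population-mean value is recorded every ``cadence``
    events; ``t_hit`` is the first recorded time the mean reaches
    ``theta`` (-1 when never).  The initial (all-tied) rank order is a
    uniformly random permutation; later ties keep insertion order, a
    measure-zero event once genotypes have mutated apart.
    """
    np.random.seed(seed)
    n = indptr.shape[0] - 1
    n_dim = start.shape[0]
    geno = np.empty((n, n_dim))
    for i in range(n):
        for j in range(n_dim):
            geno[i, j] = start[j]
    vals = np.empty(n)
    v0 = _objective_value(obj_id, start, n_dim)
    for i in range(n):
        vals[i] = v0
    val_sum = v0 * n

    # rank-fitness CDF over ranks (worst = rank 0); static under rank selection
    cum = np.empty(n)
    acc = 0.0
    for j in range(n):
        acc += (1.0 - s) + 2.0 * s * j / (n - 1.0)
        cum[j] = acc

    sorted_nodes = np.random.permutation(n)
    rank_of = np.empty(n, np.int64)
    for r in range(n):
        rank_of[sorted_nodes[r]] = r

    nrec = 0
    rec[nrec] = v0
    nrec += 1
    t_hit = -1
    if v0 >= theta:
        t_hit = 0
        if stop_at_theta:
            return nrec, t_hit

    for ev in range(1, max_events + 1):
        u = np.random.random() * cum[n - 1]
        j = np.searchsorted(cum, u, side="right")
        if j >= n:
            j = n - 1
        parent = sorted_nodes[j]
        lo = indptr[parent]
        hi = indptr[parent + 1]
        victim = indices[lo + int(np.random.random() * (hi - lo))]
        if victim != parent:
            val_sum += vals[parent] - vals[victim]
            vals[victim] = vals[parent]
            for k in range(n_dim):
                geno[victim, k] = geno[parent, k]
            _reposition(sorted_nodes, rank_of, vals, victim)
        # mutate parent or offspring with equal probability
        target = parent if np.random.random() < 0.5 else victim
        for k in range(n_dim):
            geno[target, k] += sigma * np.random.normal()
        new_v = _objective_value(obj_id, geno[target], n_dim)
        val_sum += new_v - vals[target]
        vals[target] = new_v
        _reposition(sorted_nodes, rank_of, vals, target)

        if ev % cadence == 0:
            val_sum = 0.0  # fresh sum at record points avoids float drift
            for i in range(n):
                val_sum += vals[i]
            mv = val_sum / n
            if nrec < rec.shape[0]:
                rec[nrec] = mv
                nrec += 1
            if mv >= theta and t_hit < 0:
                t_hit = ev
                if stop_at_theta:
                    break
    return nrec, t_hit


def evolve_on_graph(graph: nx.Graph, problem: OptProblem, n_replicates: int,
                    seed=None, max_events: int = 2_000_000,
                    cadence: int | None = None, stop_at_threshold: bool = True):
    """Run replicate rank-selection Bd optimizations on a graph.

    Returns a list of :class:`OptTrajectory`.  A replicate that never
    reaches the threshold within ``max_events`` is marked censored (when
    a threshold is set at all).  Replicates get independent seeds derived
    from the master seed.
    """
    validate_graph(graph, require_connected=True)
    indptr, indices = graph_to_csr(graph)
    n = graph.number_of_nodes()
    cadence = cadence or n
    rng = np.random.default_rng(seed)
    theta = problem.theta if problem.theta is not None else math.inf
    rec = np.empty(max_events // cadence + 1)
    out = []
    for rep in range(n_replicates):
        kseed = int(rng.integers(1, 2**31))
        nrec, t_hit = _evolve(
            indptr, indices, float(problem.s), _OBJ[problem.objective],
            float(problem.sigma), problem.start.astype(float), cadence,
            max_events, theta, stop_at_threshold, kseed, rec,
        )
        censored = problem.theta is not None and t_hit < 0
        out.append(
            OptTrajectory(
                replicate=rep,
                times=np.arange(nrec) * cadence,
                mean_values=rec[:nrec].copy(),
                time_to_threshold=None if t_hit < 0 else int(t_hit),
                censored=censored,
                theta=problem.theta,
            )
        )
    return out


def time_to_threshold(traj: OptTrajectory, theta: float):
    """First recorded time (events) with mean value >= theta; None if censored."""
    hit = np.nonzero(traj.mean_values >= theta)[0]
    if hit.size == 0:
        return None
    return int(traj.times[hit[0]])


def mean_time_to_threshold(trajectories, theta: float | None = None):
    """Mean time-to-threshold over non-censored replicates.

    Returns (mean_events, n_used, n_censored); censored replicates are
    excluded from the mean and reported.
    """
    times = []
    censored = 0
    for traj in trajectories:
        t = time_to_threshold(traj, theta if theta is not None else traj.theta)
        if t is None:
            censored += 1
        else:
            times.append(t)
    mean = float(np.mean(times)) if times else math.nan
    return mean, len(times), censored
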