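"""Reproducible study drivers combining the generator, simulator and theory.

These functions assemble the package's headline experiments end to end:
sweep the triangle fraction of 5-regular graphs, measure fixation
statistics or optimization times, and relate them to the pair-
approximation acceleration factor 1 - F.  They exist so the test suite
and the reproduction script exercise exactly the same code paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import generate, moran, optimize, theory

__all__ = [
    "phi_sweep_graphs",
    "fixation_sweep",
    "quadratic_time_sweep",
    "acceleration_correlation",
    "rastrigin_crossover",
]


def phi_sweep_graphs(phis, n: int = 100, k: int = 5, *, budget: int | None = None,
                     tol: float | None = None, seed=None):
    """k-regular graphs of size n annealed to each target triangle fraction.

    The default runs the full k-million-proposal schedule with no early
    stop, so each returned graph is (close to) a stationary sample of the
    swap chain at its target; pass a smaller ``budget`` and a ``tol`` for
    quick, greedier generation.
    """
    rng = np.random.default_rng(seed)
    return {
        phi: generate.tuned_regular_graph(
            n, k, phi, budget=budget, tol=tol, seed=int(rng.integers(2**31))
        )
        for phi in phis
    }


def fixation_sweep(graphs: dict, s: float, rule: str, n_mc: int, seed=None) -> dict:
    """Fixation estimates per graph in a phi-keyed graph dict."""
    rng = np.random.default_rng(seed)
    out = {}
    for phi, g in graphs.items():
        cfg = moran.MoranConfig(s=s, rule=rule)
        out[phi] = moran.estimate_fixation(g, cfg, n_mc, seed=int(rng.integers(2**31)))
    return out


@dataclass
class QuadraticSweepResult:
    """Mean time-to-threshold against the acceleration factor, per graph."""

    phis: np.ndarray            # achieved triangle fractions
    accelerations: np.ndarray   # 1 - F at the achieved phi
    mean_times: np.ndarray      # events to mean value >= theta
    n_used: np.ndarray
    n_censored: np.ndarray

    @property
    def pearson_r(self) -> float:
        ok = np.isfinite(self.mean_times)
        return float(np.corrcoef(self.accelerations[ok], self.mean_times[ok])[0, 1])


def quadratic_time_sweep(graphs: dict, *, k: int = 5, n_replicates: int = 100,
                         max_events: int = 2_000_000, seed=None) -> QuadraticSweepResult:
    """Rank-selection Bd optimization of the quadratic landscape per graph.

    Measures the mean time (events) for the population-mean objective
    value to reach the problem threshold, and pairs it with the analytic
    acceleration factor 1 - F of each graph's *achieved* transitivity.
    """
    from .graphs import transitivity

    rng = np.random.default_rng(seed)
    problem = optimize.OptProblem(objective="quadratic")
    phis, accel, times, used, censored = [], [], [], [], []
    for _, g in sorted(graphs.items()):
        phi = transitivity(g)
        trajs = optimize.evolve_on_graph(
            g, problem, n_replicates, seed=int(rng.integers(2**31)),
            max_events=max_events,
        )
        mean_t, n_used, n_cens = optimize.mean_time_to_threshold(trajs)
        phis.append(phi)
        accel.append(theory.inbreeding_F(k, phi).acceleration)
        times.append(mean_t)
        used.append(n_used)
        censored.append(n_cens)
    return QuadraticSweepResult(
        phis=np.array(phis),
        accelerations=np.array(accel),
        mean_times=np.array(times),
        n_used=np.array(used),
        n_censored=np.array(censored),
    )


def acceleration_correlation(phis=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5), *, n: int = 100,
                             k: int = 5, n_replicates: int = 100,
                             anneal_budget: int | None = None,
                             max_events: int = 2_000_000, seed=None):
    """End-to-end: generate the phi sweep, time the quadratic optimization,
    return (QuadraticSweepResult, graphs)."""
    rng = np.random.default_rng(seed)
    graphs = phi_sweep_graphs(phis, n=n, k=k, budget=anneal_budget,
                              seed=int(rng.integers(2**31)))
    result = quadratic_time_sweep(graphs, k=k, n_replicates=n_replicates,
                                  max_events=max_events,
                                  seed=int(rng.integers(2**31)))
    return result, graphs


def rastrigin_crossover(graph_low, graph_high, *, n_replicates: int = 40,
                        max_events: int = 400_000, seed=None):
    """Mean Rastrigin trajectories on a low-phi and a high-phi graph.

    Returns (times, mean_low, mean_high): the ensemble-mean population
    objective value on the shared recording grid for each graph.  The
    smooth-landscape ordering reverses here: the low-phi (accelerator-
    like) graph converges faster early, the high-phi graph explores the
    rugged landscape more and overtakes late.
    """
    rng = np.random.default_rng(seed)
    problem = optimize.OptProblem(objective="rastrigin", theta=None)
    curves = []
    for g in (graph_low, graph_high):
        trajs = optimize.evolve_on_graph(
            g, problem, n_replicates, seed=int(rng.integers(2**31)),
            max_events=max_events, stop_at_threshold=False,
        )
        length = min(t.mean_values.size for t in trajs)
        curves.append(np.mean([t.mean_values[:length] for t in trajs], axis=0))
        times = trajs[0].times[:length]
    length = min(c.size for c in curves)
    return times[:length], curves[0][:length], curves[1][:length]
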