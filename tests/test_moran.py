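"""Moran dynamics: exact solver, Monte Carlo estimates, bookkeeping."""

import math

import networkx as nx
import numpy as np
import pytest

import evomotif as em
from evomotif.moran import _sim, graph_to_csr, _RULES

from conftest import random_connected_graph


class TestExactSolver:
    def test_neutral_triangle_hand_solution(self):
        """Doob h-transform of the neutral K3 chain: P = 1/3, T|fix = 4 events."""
        for rule in ("Bd", "dB"):
            sol = em.exact_small_graph_solve(nx.complete_graph(3), 0.0, rule)
            assert sol.probability == pytest.approx(1 / 3, abs=1e-10)
            assert sol.cond_time_events == pytest.approx(4.0, abs=1e-9)

    @pytest.mark.parametrize("graph", [nx.cycle_graph(6), nx.complete_graph(4),
                                       nx.random_regular_graph(3, 8, seed=1)])
    def test_isothermal_neutral_probability(self, graph):
        """Regular graphs have uniform-start neutral fixation probability 1/N."""
        n = graph.number_of_nodes()
        for rule in ("Bd", "dB"):
            sol = em.exact_small_graph_solve(graph, 0.0, rule)
            assert sol.probability == pytest.approx(1 / n, abs=1e-10)
            # node-transitive symmetry is not required; only the average is 1/N

    @pytest.mark.parametrize("n,s", [(4, 0.1), (6, 0.3), (8, 0.05)])
    def test_complete_graph_matches_wellmixed_chain(self, n, s):
        """Two independent constructions of the same chain must agree."""
        sol = em.exact_small_graph_solve(nx.complete_graph(n), s, "Bd")
        assert sol.probability == pytest.approx(em.wellmixed_fixation_prob(n, s, 1 / n), abs=1e-9)
        assert sol.cond_time_events == pytest.approx(
            em.wellmixed_conditional_time(n, s, 1 / n), rel=1e-9
        )

    def test_state_space_cap(self):
        with pytest.raises(ValueError, match="state space too big"):
            em.exact_small_graph_solve(nx.cycle_graph(15), 0.0, "Bd")


class TestMonteCarlo:
    @pytest.mark.parametrize("rule", ["Bd", "dB"])
    @pytest.mark.parametrize("s", [0.0, 0.2])
    def test_matches_exact_solver(self, rule, s, rng):
        g = random_connected_graph(7, 0.45, rng)
        sol = em.exact_small_graph_solve(g, s, rule)
        est = em.estimate_fixation(
            g, em.MoranConfig(s=s, rule=rule), 20_000, seed=int(rng.integers(2**31))
        )
        assert abs(est.probability - sol.probability) <= 4 * est.se
        assert abs(est.cond_time_events - sol.cond_time_events) <= 4 * est.cond_time_se_events

    def test_binomial_standard_error_attached(self, rng):
        g = nx.complete_graph(5)
        est = em.estimate_fixation(g, em.MoranConfig(s=0.0), 400, seed=3)
        assert est.se == pytest.approx(
            math.sqrt(est.probability * (1 - est.probability) / 400)
        )
        assert est.n_fixed + est.n_lost + est.n_censored == est.n_replicates

    def test_seed_reproducibility(self):
        g = em.random_regular(30, 4, seed=2)
        cfg = em.MoranConfig(s=0.05, rule="dB")
        e1 = em.estimate_fixation(g, cfg, 500, seed=11)
        e2 = em.estimate_fixation(g, cfg, 500, seed=11)
        assert e1 == e2

    def test_absorbing_initial_conditions(self):
        g = nx.cycle_graph(6)
        out, events, _ = em.run_to_absorption(g, em.MoranConfig(init=1.0), seed=0)
        assert out == "fixed" and events == 0
        out, events, _ = em.run_to_absorption(g, em.MoranConfig(init=[]), seed=0)
        assert out == "lost" and events == 0

    def test_censoring_reported_separately(self):
        g = em.random_regular(50, 4, seed=5)
        cfg = em.MoranConfig(s=0.0, init=0.5, max_events=10)
        out, events, _ = em.run_to_absorption(g, cfg, seed=1)
        assert out == "censored" and events == 10
        est = em.estimate_fixation(g, cfg, 50, seed=1)
        assert est.n_censored == 50
        assert math.isnan(est.cond_time_events)
        assert not est.usable

    def test_strong_selection_two_node_path(self):
        """With s huge, the single mutant on P2 reproduces and fixes immediately."""
        g = nx.path_graph(2)
        cfg = em.MoranConfig(s=1e9, init=[0])
        fixed = sum(
            em.run_to_absorption(g, cfg, seed=i)[0] == "fixed" for i in range(200)
        )
        assert fixed >= 198


class TestEdgeBookkeeping:
    def test_incremental_mixed_count_audits_against_recount(self, rng):
        g = random_connected_graph(15, 0.3, rng)
        indptr, indices = graph_to_csr(g)
        for rep in range(20):
            types = np.zeros(g.number_of_nodes(), np.int8)
            types[rng.choice(g.number_of_nodes(), 5, replace=False)] = 1
            out, events, _, mixed = _sim(
                indptr, indices, types, 0.1, _RULES["Bd"], 200,
                int(rng.integers(1, 2**31)), 1, np.empty(0), np.empty(0),
            )
            recount = sum(1 for u, v in g.edges if types[u] != types[v])
            assert mixed == recount

    def test_recorded_identities_on_regular_graph(self, rng):
        """p_aa = p_a - p_Aa and p_AA = (1-p_a) - p_Aa stay non-negative,
        and p_a moves by at most 1/N per event."""
        g = em.random_regular(20, 4, seed=8)
        cfg = em.MoranConfig(s=0.1, record=True, cadence=1, init=0.3)
        _, _, traj = em.run_to_absorption(g, cfg, seed=9)
        assert np.all(traj.p_aa >= -1e-12)
        assert np.all(traj.p_AA >= -1e-12)
        assert np.all(np.abs(np.diff(traj.p_a)) <= 1 / 20 + 1e-12)
        assert traj.p_Aa[-1] == 0.0  # no mixed edges at absorption

    def test_ensemble_trajectories_conditioned_on_fixation(self):
        g = em.random_regular(30, 4, seed=3)
        ens = em.record_mean_trajectories(
            g, em.MoranConfig(s=0.3, record=True), 400, seed=4
        )
        assert ens.n_fixed > 0
        assert ens.mean_p_a[-1] > 0.9  # fixing runs end near p_a = 1
        assert np.all(ens.mean_p_Aa >= 0)
        assert ens.times[0] == 0


class TestConfigValidation:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            em.MoranConfig(s=-1.5)
        with pytest.raises(ValueError):
            em.MoranConfig(rule="bD")
        with pytest.raises(ValueError):
            em.MoranConfig(max_events=0)

    def test_disconnected_graph_rejected(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        with pytest.raises(ValueError, match="not connected"):
            em.estimate_fixation(g, em.MoranConfig(), 10)
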