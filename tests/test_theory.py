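"""Closed forms: inbreeding parameter, diffusion solutions, drift terms."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import evomotif as em
from evomotif.theory import PairState


class TestInbreedingF:
    @pytest.mark.parametrize(
        "k,phi,f", [(5, 0.0, 0.25), (5, 0.5, 0.5), (3, 0.0, 0.5), (9, 0.0, 0.125)]
    )
    def test_values(self, k, phi, f):
        p = em.inbreeding_F(k, phi)
        assert p.F == pytest.approx(f)
        assert p.acceleration == pytest.approx(1 - f)
        assert not p.diverges

    def test_cycle_graph_divergence_flagged(self):
        p = em.inbreeding_F(2, 0.0)
        assert p.F == pytest.approx(1.0)
        assert p.diverges

    def test_phi_one_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            em.inbreeding_F(5, 1.0)

    def test_acceleration_never_exceeds_one(self):
        # regular graphs cannot accelerate fixation
        for k in range(2, 12):
            for phi in np.linspace(0, 0.95, 12):
                assert em.inbreeding_F(k, float(phi)).acceleration < 1.0


class TestFixationProbability:
    def test_printed_value(self):
        assert em.fixation_prob_regular(100, 0.01, 0.01) == pytest.approx(0.015741, abs=5e-7)

    def test_boundaries_and_neutral_limit(self):
        assert em.fixation_prob_regular(100, 0.0, 0.3) == 0.3
        assert em.fixation_prob_regular(50, 0.02, 1.0) == pytest.approx(1.0)
        # continuity at s -> 0
        assert em.fixation_prob_regular(100, 1e-12, 0.3) == pytest.approx(0.3, rel=1e-6)

    def test_monotone_in_s_and_p0(self):
        ss = np.linspace(0.0, 0.5, 30)
        ps = [em.fixation_prob_regular(50, float(s), 0.1) for s in ss]
        assert np.all(np.diff(ps) > 0)
        p0s = np.linspace(0.01, 1.0, 30)
        ps = [em.fixation_prob_regular(50, 0.05, float(p)) for p in p0s]
        assert np.all(np.diff(ps) > 0)

    @settings(derandomize=True, max_examples=200)
    @given(
        n=st.integers(2, 10_000),
        s=st.floats(-0.5, 0.5),
        p0=st.floats(0.0, 1.0),
    )
    def test_always_a_probability(self, n, s, p0):
        p = em.fixation_prob_regular(n, s, p0)
        assert -1e-12 <= p <= 1.0 + 1e-12

    def test_numerically_stable_for_large_ns(self):
        # |Ns| up to 1e3 must not overflow or lose the leading digits
        p = em.fixation_prob_regular(100_000, 0.01, 1e-5)
        assert p == pytest.approx(-math.expm1(-0.01) / -math.expm1(-1000.0), rel=1e-12)


class TestAmplifiedProbability:
    def test_alpha_one_recovers_regular(self):
        assert em.fixation_prob_amplified(100, 0.01, 1.0) == pytest.approx(
            em.fixation_prob_regular(100, 0.01, 0.01)
        )

    def test_printed_value(self):
        assert em.fixation_prob_amplified(100, 0.01, 0.8) == pytest.approx(0.014470, abs=5e-7)

    def test_neutral_gives_one_over_n(self):
        for alpha in (0.3, 1.0, 2.5):
            assert em.fixation_prob_amplified(80, 0.0, alpha) == pytest.approx(1 / 80)


class TestConditionalTimes:
    def test_neutral_triangle_is_four_events(self):
        assert em.wellmixed_conditional_time(3, 0.0, 1 / 3) == pytest.approx(4.0)

    def test_fixed_start_needs_no_time(self):
        assert em.wellmixed_conditional_time(10, 0.1, 1.0) == 0.0

    def test_p0_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            em.wellmixed_conditional_time(10, 0.1, 0.0)

    @pytest.mark.parametrize("n,s", [(4, 0.0), (6, 0.15), (8, 0.4)])
    def test_agrees_with_configuration_space_oracle(self, n, s):
        sol = em.exact_small_graph_solve(nx.complete_graph(n), s, "Bd")
        assert em.wellmixed_conditional_time(n, s, 1 / n) == pytest.approx(
            sol.cond_time_events, rel=1e-9
        )

    def test_pair_approximation_scaling(self):
        t0 = em.conditional_time_regular(100, 0.01, 5, 0.0)
        t5 = em.conditional_time_regular(100, 0.01, 5, 0.5)
        assert t5 / t0 == pytest.approx(1.5)  # (1-F(0))/(1-F(0.5)) = 0.75/0.5
        assert em.conditional_time_regular(100, 0.01, 3, 0.0) == pytest.approx(
            2 * em.wellmixed_conditional_time(100, 0.01, 0.01)
        )

    def test_monotone_in_phi(self):
        ts = [em.conditional_time_regular(60, 0.02, 5, p) for p in np.linspace(0, 0.6, 10)]
        assert np.all(np.diff(ts) > 0)

    def test_divergence_regime_raises(self):
        with pytest.raises(ValueError, match="diverges"):
            em.conditional_time_regular(50, 0.01, 2, 0.0)

    def test_generation_units(self):
        ev = em.wellmixed_conditional_time(20, 0.1, 0.05)
        gen = em.wellmixed_conditional_time(20, 0.1, 0.05, units="generations")
        assert ev == pytest.approx(20 * gen)


class TestDriftTerms:
    def test_neutral_node_drift_vanishes(self):
        params = em.inbreeding_F(5, 0.2)
        mu_a, _ = em.drift_terms(PairState(0.4, 0.2), params, 0.0)
        assert mu_a == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(
        k=st.integers(3, 20),
        phi=st.floats(0.0, 0.9),
        pa=st.floats(0.01, 0.99),
    )
    def test_equilibrium_is_fixed_point(self, k, phi, pa):
        """The edge drift's leading term vanishes at p_Aa = (1-F) p_A p_a."""
        params = em.inbreeding_F(k, phi)
        paa = max(params.acceleration, 0.0) * (1 - pa) * pa
        _, mu_paa = em.drift_terms(PairState(pa, paa), params, 0.05)
        assert mu_paa == pytest.approx(0.0, abs=1e-12)

    def test_uncorrelated_edges_decay(self):
        # k=5, phi=0, p_Aa = p_A p_a: leading term is -p_Aa / 5
        state = PairState(0.5, 0.25)
        _, mu_paa = em.drift_terms(state, em.inbreeding_F(5, 0.0), 0.0)
        assert mu_paa == pytest.approx(-0.25 / 5)

    def test_inconsistent_absorbing_state_rejected(self):
        with pytest.raises(ValueError):
            PairState(0.0, 0.1)
        with pytest.raises(ValueError):
            PairState(1.0, 0.05)
        # boundary states with no mixed edges are fine and have zero drift
        mu_a, mu_paa = em.drift_terms(PairState(1.0, 0.0), em.inbreeding_F(5, 0.0), 0.1)
        assert mu_a == 0.0 and mu_paa == 0.0


class TestAmplificationAndErrors:
    def test_db_amplification_values(self):
        assert em.db_amplification({12: 50, 4: 50}) == pytest.approx(0.8)
        assert em.db_amplification([5] * 100) == pytest.approx(1.0)
        assert em.db_amplification({7: 1}) == pytest.approx(1.0)

    def test_db_amplification_errors(self):
        with pytest.raises(ValueError):
            em.db_amplification({})
        with pytest.raises(ValueError):
            em.db_amplification({0: 3})

    def test_mc_standard_error(self):
        assert em.mc_standard_error(0.5, 10_000) == pytest.approx(0.005)
        assert em.mc_standard_error(0.0, 100) == 0.0
        assert em.mc_standard_error(1.0, 100) == 0.0
        assert em.mc_standard_error(0.01574, 10**7) == pytest.approx(
            math.sqrt(0.01574 * 0.98426 / 1e7)
        )
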