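"""Pair-approximation and diffusion theory for fixation on graphs.

The analytic layer behind the simulations.  For a k-regular graph with
global transitivity ``phi``, the expected per-generation changes of the
mutant node frequency ``p_a`` and the mixed-edge frequency ``p_Aa`` are

    mu(dp_a)  = (s / w) * p_Aa,                                w = 1 + s p_a
    mu(dp_Aa) = (1/k) p_Aa [ (k-1)(1-phi)(1 - p_Aa/(p_A p_a)) - 1 ] + O(s).

Edge dynamics are O(1) while node dynamics are O(s): under weak selection
the edges equilibrate fast, at

    p_Aa* = (1 - F) p_A p_a,     F = 1 / ((k-1)(1-phi)),

where ``F`` plays the role of an inbreeding coefficient induced by the
graph: triangles make neighbours likely to share a recent common
ancestor, depressing the number of mixed edges.  Substituting the
equilibrium into the Kolmogorov backward equation gives the well-mixed
fixation probability (higher-order motifs do not move probabilities on
regular graphs) and a conditional fixation time stretched by 1/(1-F):

    P(p0) = (1 - exp(-N s p0)) / (1 - exp(-N s)),
    T(p0) = T_wm(p0) / (1 - F).

``1 - F`` is the *acceleration factor* (well-mixed time over structured
time); it cannot exceed one, so regular graphs never accelerate
fixation.  For degree-heterogeneous graphs the probability generalises to

    P(1/N) = (1 - exp(-alpha s)) / (1 - exp(-N alpha s))

with an amplification factor ``alpha``; under death-Birth updating
``alpha = (E[i])^2 / E[i^2]`` over the degree distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "PairState",
    "PairApproxParams",
    "inbreeding_F",
    "drift_terms",
    "fixation_prob_regular",
    "fixation_prob_amplified",
    "wellmixed_conditional_time",
    "wellmixed_fixation_prob",
    "conditional_time_regular",
    "db_amplification",
    "mc_standard_error",
]


@dataclass(frozen=True)
class PairState:
    """Mutant node frequency and mixed-edge frequency (ordered convention)."""

    p_a: float
    p_Aa: float

    def __post_init__(self):
        if not 0.0 <= self.p_a <= 1.0:
            raise ValueError("p_a must be in [0, 1]")
        if self.p_Aa < -1e-12:
            raise ValueError("p_Aa must be non-negative")
        if self.p_Aa > min(self.p_a, 1.0 - self.p_a) + 1e-12:
            raise ValueError(
                "p_Aa may not exceed min(p_a, 1-p_a): p_AA and p_aa must stay non-negative"
            )

    @property
    def p_A(self) -> float:
        return 1.0 - self.p_a

    @property
    def p_AA(self) -> float:
        return self.p_A - self.p_Aa

    @property
    def p_aa(self) -> float:
        return self.p_a - self.p_Aa


@dataclass(frozen=True)
class PairApproxParams:
    """Inbreeding-like parameter of a (k, phi) regular graph.

    ``diverges`` flags F >= 1, where the pair-approximation fixation time
    diverges (e.g. the cycle, k=2, phi=0) and no acceleration factor is
    meaningful.
    """

    k: int
    phi: float
    F: float
    acceleration: float  # 1 - F

    @property
    def diverges(self) -> bool:
        return self.F >= 1.0


def inbreeding_F(k: int, phi: float) -> PairApproxParams:
    """F = 1 / ((k-1)(1-phi)) and the acceleration factor 1-F."""
    if k < 2:
        raise ValueError("degree k must be >= 2")
    if not 0.0 <= phi < 1.0:
        if phi == 1.0:
            raise ValueError("pair approximation undefined at phi = 1")
        raise ValueError("phi must be in [0, 1)")
    f = 1.0 / ((k - 1) * (1.0 - phi))
    return PairApproxParams(k=k, phi=phi, F=f, acceleration=1.0 - f)


def drift_terms(state: PairState, params: PairApproxParams, s: float):
    """Expected one-generation changes (mu_dp_a, leading mu_dp_Aa).

    The O(s) remainder of the edge drift is excluded by contract — the
    timescale-separation argument only uses the leading term.
    """
    if state.p_a in (0.0, 1.0) and state.p_Aa != 0.0:
        raise ValueError("absorbing state with nonzero mixed-edge frequency")
    w = 1.0 + s * state.p_a
    mu_pa = s / w * state.p_Aa
    k, phi = params.k, params.phi
    if state.p_a in (0.0, 1.0):
        mu_paa = -state.p_Aa / k  # p_Aa = 0 here, so this is exactly 0
    else:
        mu_paa = (
            state.p_Aa / k
            * ((k - 1) * (1.0 - phi) * (1.0 - state.p_Aa / (state.p_A * state.p_a)) - 1.0)
        )
    return mu_pa, mu_paa


def fixation_prob_regular(n: int, s: float, p0: float) -> float:
    """Diffusion fixation probability on a regular graph (= well-mixed).

    ``(1 - exp(-N s p0)) / (1 - exp(-N s))``, with the neutral limit
    handled analytically and expm1 used for numerical stability.
    """
    if n < 2:
        raise ValueError("population size must be >= 2")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if s == 0.0:
        return p0
    if s > 0.0:
        return math.expm1(-n * s * p0) / math.expm1(-n * s)
    # deleterious mutants: rearrange so every exponent is non-positive
    x = -n * s
    return math.exp(x * (p0 - 1.0)) * math.expm1(-x * p0) / math.expm1(-x)


def fixation_prob_amplified(n: int, s: float, alpha: float) -> float:
    """Single-mutant fixation probability with amplification factor alpha.

    ``(1 - exp(-alpha s)) / (1 - exp(-N alpha s))``; ``alpha = 1``
    recovers the regular-graph formula at ``p0 = 1/N``; ``s = 0`` gives
    ``1/N`` for any alpha.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n < 2:
        raise ValueError("population size must be >= 2")
    if s == 0.0:
        return 1.0 / n
    if s > 0.0:
        return math.expm1(-alpha * s) / math.expm1(-n * alpha * s)
    y = -alpha * s  # deleterious: exponents positive, so guard the tail
    if n * y > 700.0:
        return 0.0  # below double-precision resolution
    return math.expm1(y) / math.expm1(n * y)


def _wellmixed_chain_solve(n: int, s: float):
    """Solve the (N+1)-state well-mixed Moran frequency chain.

    Returns (h, u): fixation probability and E[T * 1_fix] (events) for
    the transient mutant counts m = 1..N-1.  Self-loop transitions are
    kept, so times count every replacement event.
    """
    m = np.arange(1, n)
    up = (1.0 + s) * m / (n + s * m) * (n - m) / (n - 1)
    down = (n - m) / (n + s * m) * m / (n - 1)
    size = n - 1
    # banded (I - Q): Q has up on the super-diagonal, down on the sub-
    ab = np.zeros((3, size))
    ab[0, 1:] = -up[:-1]
    ab[1, :] = up + down
    ab[2, :-1] = -down[1:]
    b = np.zeros(size)
    b[-1] = up[-1]
    h = solve_banded((1, 1), ab, b)
    u = solve_banded((1, 1), ab, h)
    return h, u


def wellmixed_fixation_prob(n: int, s: float, p0: float) -> float:
    """Exact fixation probability of the well-mixed Moran chain."""
    m0 = _freq_index(n, p0)
    if m0 == 0:
        return 0.0
    if m0 == n:
        return 1.0
    h, _ = _wellmixed_chain_solve(n, s)
    return float(h[m0 - 1])


def wellmixed_conditional_time(n: int, s: float, p0: float, units: str = "events") -> float:
    """Exact conditional mean fixation time of the well-mixed Moran chain.

    Solves the absorbing-chain linear system for the fixation probability
    h and the h-transformed system for E[T | fixation] — not the
    diffusion approximation.  ``p0`` must be a lattice frequency m/N with
    m >= 1 (conditioning on fixation from p0 = 0 is undefined);
    ``p0 = 1`` returns 0.
    """
    if n < 2:
        raise ValueError("population size must be >= 2")
    m0 = _freq_index(n, p0)
    if m0 == 0:
        raise ValueError("conditional fixation time undefined at p0 = 0")
    if m0 == n:
        t = 0.0
    else:
        h, u = _wellmixed_chain_solve(n, s)
        t = float(u[m0 - 1] / h[m0 - 1])
    if units == "generations":
        return t / n
    if units != "events":
        raise ValueError("units must be 'events' or 'generations'")
    return t


def _freq_index(n: int, p0: float) -> int:
    m0 = p0 * n
    if abs(m0 - round(m0)) > 1e-9:
        raise ValueError("p0 must be a lattice frequency m/N")
    return int(round(m0))


def conditional_time_regular(n: int, s: float, k: int, phi: float, p0: float | None = None,
                             units: str = "events") -> float:
    """Pair-approximation conditional fixation time on a (k, phi) regular graph.

    ``T = T_wm(p0) / (1 - F)``; raises when F >= 1 (time divergence
    regime).  ``p0`` defaults to a single mutant, 1/N.
    """
    params = inbreeding_F(k, phi)
    if params.diverges:
        raise ValueError(
            f"pair-approximation time diverges: F = {params.F:.3f} >= 1 for k={k}, phi={phi}"
        )
    if p0 is None:
        p0 = 1.0 / n
    return wellmixed_conditional_time(n, s, p0, units=units) / params.acceleration


def db_amplification(degrees) -> float:
    """death-Birth amplification factor (E[i])^2 / E[i^2].

    ``degrees`` is either a mapping {degree: count} or a sequence of node
    degrees.  Equals 1 exactly for regular graphs and decreases with
    degree variance.
    """
    if hasattr(degrees, "items"):
        ks = np.array(list(degrees.keys()), float)
        ws = np.array(list(degrees.values()), float)
    else:
        ks = np.asarray(list(degrees), float)
        ws = np.ones_like(ks)
    if ks.size == 0 or ws.sum() <= 0:
        raise ValueError("empty degree histogram")
    if (ks <= 0).any():
        raise ValueError("degrees must be positive")
    e1 = float((ks * ws).sum() / ws.sum())
    e2 = float((ks**2 * ws).sum() / ws.sum())
    return e1 * e1 / e2


def mc_standard_error(p_mc: float, n_mc: int) -> float:
    """Binomial standard error sqrt(P (1-P) / n) of a Monte Carlo fixation estimate."""
    if not 0.0 <= p_mc <= 1.0:
        raise ValueError("p_mc must be in [0, 1]")
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    return math.sqrt(p_mc * (1.0 - p_mc) / n_mc)
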