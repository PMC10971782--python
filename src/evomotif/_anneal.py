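"""Numba kernel for the annealed edge-swap chains.

Degrees are invariant under every swap the chains propose, so the
adjacency can live in fixed-width neighbour lists plus a dense boolean
membership matrix, giving O(k) triangle-count deltas and O(1) joint-
degree-product deltas per proposal.  The kernel implements both
acceptance criteria (Gaussian Metropolis--Hastings on the tracked
metric, and the always-toward / gamma-away rule used for 2K rewiring)
and both proposal schemes (any edge pair with random orientation, or
same-degree-type pairs with the type-conserving pairing).
"""

from __future__ import annotations

import numpy as np
from numba import njit

METRIC_PHI = 0
METRIC_ASSORT = 1
MODE_GAUSSIAN = 0
MODE_GAMMA = 1


@njit(cache=True)
def _common_excl(nbr, deg, adjm, a, c, x1, x2):
    """|(N(a) \\ {x1}) & (N(c) \\ {x2})| via the membership matrix."""
    cnt = 0
    for t in range(deg[a]):
        x = nbr[a, t]
        if x != x1 and x != x2 and adjm[c, x]:
            cnt += 1
    return cnt


@njit(cache=True)
def _tri_delta(nbr, deg, adjm, a, b, c, d):
    """Triangle change of rewiring (a,b),(c,d) -> (a,c),(b,d)."""
    removed = _common_excl(nbr, deg, adjm, a, b, -1, -1) + _common_excl(nbr, deg, adjm, c, d, -1, -1)
    added = _common_excl(nbr, deg, adjm, a, c, b, d) + _common_excl(nbr, deg, adjm, b, d, a, c)
    return added - removed


@njit(cache=True)
def _replace_neighbor(nbr, deg, u, old, new):
    for t in range(deg[u]):
        if nbr[u, t] == old:
            nbr[u, t] = new
            return


@njit(cache=True)
def _apply(nbr, deg, adjm, edges, i, j, a, b, c, d):
    """Rewire (a,b),(c,d) -> (a,c),(b,d); slots i -> (a,c), j -> (b,d)."""
    adjm[a, b] = adjm[b, a] = False
    adjm[c, d] = adjm[d, c] = False
    adjm[a, c] = adjm[c, a] = True
    adjm[b, d] = adjm[d, b] = True
    _replace_neighbor(nbr, deg, a, b, c)
    _replace_neighbor(nbr, deg, c, d, a)
    _replace_neighbor(nbr, deg, b, a, d)
    _replace_neighbor(nbr, deg, d, c, b)
    edges[i, 0] = a
    edges[i, 1] = c
    edges[j, 0] = b
    edges[j, 1] = d


@njit(cache=True)
def _connected(nbr, deg, stack, mark, stamp):
    n = deg.shape[0]
    top = 0
    stack[top] = 0
    top += 1
    mark[0] = stamp
    seen = 1
    while top > 0:
        top -= 1
        u = stack[top]
        for t in range(deg[u]):
            v = nbr[u, t]
            if mark[v] != stamp:
                mark[v] = stamp
                seen += 1
                stack[top] = v
                top += 1
    return seen == n


@njit(cache=True)
def anneal_chain(
    nbr, deg, adjm, edges,
    tri0, wedges, sjk0, assort_mu, assort_var,
    metric_id, mode_id, two_k,
    etype, bucket_start, bucket_items,
    target, sigma0, sigma_growth, sigma_interval,
    gamma0, gamma_decay, gamma_interval,
    budget, tol, has_tol, seed,
    best_edges,
):
    """Run the annealed swap chain; returns (best_err, consumed, best_tri).

    ``best_edges`` receives the edge list of the best state visited.
    The chain state left in the in/out arrays is the *final* state, which
    callers normally discard in favour of ``best_edges``.
    """
    np.random.seed(seed)
    n_edges = edges.shape[0]
    tri = tri0
    sjk = sjk0
    if metric_id == METRIC_PHI:
        value = 3.0 * tri / wedges if wedges > 0 else 0.0
    else:
        value = (sjk / n_edges - assort_mu * assort_mu) / assort_var

    sigma = sigma0
    gamma = gamma0
    best_err = abs(value - target)
    best_tri = tri
    for e in range(n_edges):
        best_edges[e, 0] = edges[e, 0]
        best_edges[e, 1] = edges[e, 1]

    n = deg.shape[0]
    stack = np.empty(n, np.int64)
    mark = np.zeros(n, np.int64)
    stamp = 0

    consumed = 0
    invalid_streak = 0
    while consumed < budget:
        i = int(np.random.random() * n_edges)
        if two_k:
            t = etype[i]
            lo = bucket_start[t]
            hi = bucket_start[t + 1]
            if hi - lo < 2:
                invalid_streak += 1
                if invalid_streak > 50_000:
                    break
                continue
            j = bucket_items[lo + int(np.random.random() * (hi - lo))]
            if j == i:
                continue
            u1 = edges[i, 0]
            v1 = edges[i, 1]
            u2 = edges[j, 0]
            v2 = edges[j, 1]
            # orient both edges low-degree end first
            if deg[u1] > deg[v1]:
                u1, v1 = v1, u1
            if deg[u2] > deg[v2]:
                u2, v2 = v2, u2
            if deg[u1] == deg[v1] and np.random.random() < 0.5:
                u2, v2 = v2, u2
            # the cross pairing (u1,v2),(v1,u2) conserves the joint degrees
            a, b, c, d = u1, v1, v2, u2
        else:
            j = int(np.random.random() * n_edges)
            if i == j:
                continue
            u1 = edges[i, 0]
            v1 = edges[i, 1]
            u2 = edges[j, 0]
            v2 = edges[j, 1]
            if np.random.random() < 0.5:
                u2, v2 = v2, u2
            a, b, c, d = u1, v1, u2, v2

        if a == c or a == d or b == c or b == d or adjm[a, c] or adjm[b, d]:
            invalid_streak += 1
            if invalid_streak > 50_000:
                break
            continue
        invalid_streak = 0
        consumed += 1

        d_tri = _tri_delta(nbr, deg, adjm, a, b, c, d)
        if metric_id == METRIC_PHI:
            dv = 3.0 * d_tri / wedges if wedges > 0 else 0.0
        else:
            d_sjk = (deg[a] * deg[c] + deg[b] * deg[d]) - (deg[a] * deg[b] + deg[c] * deg[d])
            dv = d_sjk / n_edges / assort_var

        new = value + dv
        err_old = abs(value - target)
        err_new = abs(new - target)
        if err_new <= err_old:
            accept = True
        elif mode_id == MODE_GAUSSIAN:
            accept = np.random.random() <= np.exp(
                (err_old * err_old - err_new * err_new) / (2.0 * sigma * sigma)
            )
        else:
            accept = np.random.random() <= gamma

        if accept:
            _apply(nbr, deg, adjm, edges, i, j, a, b, c, d)
            stamp += 1
            if not _connected(nbr, deg, stack, mark, stamp):
                # revert; the proposal still consumed budget
                _apply(nbr, deg, adjm, edges, i, j, a, c, b, d)
            else:
                value = new
                tri += d_tri
                if metric_id == METRIC_ASSORT:
                    sjk += (deg[a] * deg[c] + deg[b] * deg[d]) - (
                        deg[a] * deg[b] + deg[c] * deg[d]
                    )
                if err_new < best_err:
                    best_err = err_new
                    best_tri = tri
                    for e in range(n_edges):
                        best_edges[e, 0] = edges[e, 0]
                        best_edges[e, 1] = edges[e, 1]
                    if has_tol and best_err <= tol:
                        break

        if consumed % sigma_interval == 0:
            sigma *= sigma_growth
        if mode_id == MODE_GAMMA and consumed % gamma_interval == 0:
            gamma *= gamma_decay

    return best_err, consumed, best_tri
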