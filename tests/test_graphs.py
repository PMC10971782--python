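"""Motif counting, mixing statistics and edge-swap primitives."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

import evomotif as em
from evomotif.graphs import SwapRejected, EdgeTypeMismatch, edge_type

from conftest import random_connected_graph


def brute_force_motifs(g):
    """Independent triple-enumeration oracle for wedges and triangles."""
    wedges = triangles = 0
    for trio in combinations(g.nodes, 3):
        e = sum(1 for u, v in combinations(trio, 2) if g.has_edge(u, v))
        if e == 3:
            triangles += 1
            wedges += 3  # a closed triple contains three wedges
        elif e == 2:
            wedges += 1
    return wedges, triangles


@pytest.mark.parametrize(
    "build,expect",
    [
        (lambda: nx.complete_graph(4), dict(triangles=4, wedges=12, phi=1.0)),
        (lambda: nx.cycle_graph(5), dict(triangles=0, wedges=5, phi=0.0)),
        (lambda: _k4_minus_edge(), dict(triangles=2, wedges=8, phi=0.75)),
    ],
    ids=["complete-K4", "5-cycle", "K4-minus-edge"],
)
def test_count_motifs_examples(build, expect):
    p = em.count_motifs(build())
    assert p.triangles == expect["triangles"]
    assert p.wedges == expect["wedges"]
    assert p.transitivity == pytest.approx(expect["phi"])
    assert sum(p.joint_degrees.values()) == p.n_edges


def _k4_minus_edge():
    g = nx.complete_graph(4)
    g.remove_edge(2, 3)
    return g


def test_count_motifs_matches_triple_enumeration(rng):
    """Exact agreement with brute-force triple enumeration on 100 random graphs."""
    for _ in range(100):
        n = int(rng.integers(4, 13))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.8)), seed=int(rng.integers(2**31)))
        g.add_nodes_from(range(n))
        if g.number_of_edges() == 0:
            continue
        wedges, triangles = brute_force_motifs(g)
        p = em.count_motifs(g)
        assert p.wedges == wedges
        assert p.triangles == triangles
        if wedges > 0:
            assert p.transitivity == pytest.approx(3 * triangles / wedges)
            assert 0.0 <= p.transitivity <= 1.0
        else:
            assert math.isnan(p.transitivity)


def test_count_motifs_rejects_empty_graph():
    with pytest.raises(ValueError, match="no nodes"):
        em.count_motifs(nx.Graph())


def test_assortativity_star_is_minus_one():
    assert em.assortativity(nx.star_graph(5)) == pytest.approx(-1.0)


def test_assortativity_undefined_for_regular_graphs():
    # sentinel, never 0: the Pearson coefficient has zero variance
    assert math.isnan(em.assortativity(nx.cycle_graph(6)))
    assert math.isnan(em.assortativity(nx.complete_graph(5)))


def test_assortativity_perfectly_assorted_classes():
    # only within-class edges (degree 4 with degree 4, degree 2 with degree 2)
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(3))
    assert em.assortativity(g) == pytest.approx(1.0)


def test_assortativity_matches_networkx(rng):
    for _ in range(20):
        g = random_connected_graph(12, 0.35, rng)
        r = em.assortativity(g)
        if math.isnan(r):
            continue
        assert r == pytest.approx(nx.degree_assortativity_coefficient(g), abs=1e-10)


def test_connected_required_flag():
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(5))
    with pytest.raises(ValueError, match="not connected"):
        em.validate_graph(g, require_connected=True)
    assert not em.is_connected(g)
    assert em.is_connected(nx.cycle_graph(5))
    path = nx.cycle_graph(5)
    path.remove_edge(0, 1)
    assert em.is_connected(path)


def test_double_edge_swap_preserves_degrees():
    g = nx.cycle_graph(8)
    h = em.double_edge_swap(g, (0, 1), (4, 5))
    assert dict(h.degree) == dict(g.degree)
    assert h.number_of_edges() == g.number_of_edges()
    assert not h.has_edge(0, 1) and h.has_edge(0, 4) and h.has_edge(1, 5)


def test_double_edge_swap_rejections():
    with pytest.raises(SwapRejected):
        em.double_edge_swap(nx.complete_graph(4), (0, 1), (2, 3))  # parallel edge
    with pytest.raises(SwapRejected):
        em.double_edge_swap(nx.cycle_graph(6), (0, 1), (1, 2))  # shared endpoint
    with pytest.raises(ValueError, match="not in graph"):
        em.double_edge_swap(nx.cycle_graph(6), (0, 2), (3, 4))


def test_two_k_swap_preserves_joint_degrees(small_two_class_graph):
    g = small_two_class_graph
    deg = dict(g.degree)
    edges = list(g.edges)
    by_type = {}
    for e in edges:
        by_type.setdefault(tuple(sorted((deg[e[0]], deg[e[1]]))), []).append(e)
    pair = None
    for t, es in by_type.items():
        for e1, e2 in combinations(es, 2):
            if len({*e1, *e2}) == 4:
                try:
                    h = em.two_k_swap(g, e1, e2)
                except SwapRejected:
                    continue
                assert em.joint_degree_matrix(h) == em.joint_degree_matrix(g)
                assert em.assortativity(h) == pytest.approx(em.assortativity(g))
                pair = (e1, e2)
                break
        if pair:
            break
    assert pair is not None


def test_two_k_swap_type_mismatch(small_two_class_graph):
    g = small_two_class_graph
    deg = dict(g.degree)
    e_high = next(e for e in g.edges if deg[e[0]] == deg[e[1]] == 6)
    e_low = next(e for e in g.edges if deg[e[0]] == deg[e[1]] == 4)
    with pytest.raises(EdgeTypeMismatch, match="type mismatch"):
        em.two_k_swap(g, e_high, e_low)
    assert edge_type(g, e_high) == (6, 6)


def test_random_swap_sequences_conserve_invariants(rng):
    """Accepted double swaps conserve the degree sequence; phi stays in [0, 1]."""
    g = random_connected_graph(30, 0.2, rng)
    degrees = sorted(d for _, d in g.degree)
    accepted = 0
    while accepted < 1000:
        edges = list(g.edges)
        i, j = rng.integers(len(edges), size=2)
        if i == j:
            continue
        try:
            g = em.double_edge_swap(
                g, edges[i], edges[j],
                orientation="parallel" if rng.integers(2) else "crossed",
            )
        except SwapRejected:
            continue
        accepted += 1
        if accepted % 100 == 0:
            assert sorted(d for _, d in g.degree) == degrees
            phi = em.transitivity(g)
            assert 0.0 <= phi <= 1.0
    assert sorted(d for _, d in g.degree) == degrees


def test_validate_graph_rejects_self_loops_and_bad_labels():
    g = nx.Graph([(0, 0), (0, 1)])
    with pytest.raises(ValueError, match="elf-loop"):
        em.validate_graph(g)
    with pytest.raises(ValueError, match="contiguous"):
        em.validate_graph(nx.Graph([(1, 2)]))
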