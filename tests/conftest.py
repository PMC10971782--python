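import warnings

import networkx as nx
import numpy as np
import pytest

import evomotif as em


@pytest.fixture(autouse=True)
def _quiet_anneal_warnings():
    # best-found warnings are part of the API; tests assert on results instead
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240315)


def random_connected_graph(n, p, rng):
    """Connected Erdos-Renyi sample (resampled until connected)."""
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() >= 1 and nx.is_connected(g):
            return g


@pytest.fixture(scope="session")
def small_two_class_graph():
    spec = em.DegreeClassSpec(classes=[(30, 6), (30, 4)])
    return em.build_two_class_graph(spec, seed=5)
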