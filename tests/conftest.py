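import numpy as np
import pytest

from neuroqueue import DirectedNetwork, SimParams


@pytest.fixture
def chain3():
    """The 3-node, 2-pathway walkthrough network."""
    return DirectedNetwork.from_edges(("1", "2", "3"), [("1", "2"), ("2", "3")])


@pytest.fixture
def two_node_reciprocal():
    return DirectedNetwork.from_edges(("a", "b"), [("a", "b"), ("b", "a")])


@pytest.fixture
def ring5():
    labels = tuple("abcde")
    edges = [(labels[i], labels[(i + 1) % 5]) for i in range(5)]
    return DirectedNetwork.from_edges(labels, edges)


def random_simulable_network(rng: np.random.Generator, n: int, p: float) -> DirectedNetwork:
    """Small random directed graph where every node has an efferent edge."""
    for _ in range(200):
        adj = (rng.random((n, n)) < p).astype(np.int8)
        np.fill_diagonal(adj, 0)
        if adj.sum(axis=1).min() >= 1:
            return DirectedNetwork(tuple(f"v{i}" for i in range(n)), adj)
    raise RuntimeError("could not draw a simulable graph")


def short_params(seed: int, **overrides) -> SimParams:
    defaults = dict(
        rate_gen=1.0,
        rate_service=1.0,
        buffer_capacity=3,
        duration=200.0,
        transient=20.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimParams(**defaults)
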