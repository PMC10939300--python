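"""Shared fixtures: small synthetic studies and hand-built toy objects."""

from __future__ import annotations

import numpy as np
import pytest

from eabench.containers import FunctionalNetwork, GeneSetCollection, TermGraph
from eabench.synthetic import SyntheticSpec, make_network, plant_pathways


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(
        seed=17,
        n_genes=500,
        mean_degree=8,
        n_pathways=8,
        pathway_size_range=(15, 30),
        n_related_pairs=2,
        cross_links=30,
    )


@pytest.fixture(scope="session")
def small_study(small_spec):
    """A small planted study: (network, collection, ground-truth pairs)."""
    net = make_network(small_spec)
    collection, truth = plant_pathways(net, small_spec)
    return net, collection, truth


@pytest.fixture()
def toy_net() -> FunctionalNetwork:
    """Hand-built network: a1-b1, a1-b2, c-a1, c-b1 plus a spare edge."""
    return FunctionalNetwork(
        [
            ("a1", "b1", 1.0),
            ("a1", "b2", 1.0),
            ("c", "a1", 1.0),
            ("c", "b1", 1.0),
            ("x", "y", 1.0),
        ]
    )


@pytest.fixture()
def chain_graph() -> TermGraph:
    """Two-term chain: c --is_a--> r."""
    return TermGraph({"c": {("r", "is_a")}, "r": set()})


def random_toy_network(rng: np.random.Generator, n_nodes: int = 20, p: float = 0.2):
    """Erdos-Renyi style toy for brute-force comparisons."""
    net = FunctionalNetwork()
    names = [f"n{i}" for i in range(n_nodes)]
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                net.add_edge(names[i], names[j], 1.0)
    return net, names
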