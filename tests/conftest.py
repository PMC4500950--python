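import itertools

import networkx as nx
import numpy as np
import pytest

from chromnet import PlantedMotif, SimSpec, simulate_condition
from chromnet.network import network_from_edges
from chromnet.states import annotate_network


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def planted_bundle():
    """Small synthetic condition with 12 planted (Strong,Strong,Poised) FFLs."""
    spec = SimSpec(
        n_tfs=40,
        n_genes=160,
        planted_motifs=[
            PlantedMotif(("StrongActivity", "StrongActivity", "Poised"), 12)
        ],
        seed=11,
    )
    return simulate_condition(spec)


@pytest.fixture(scope="session")
def planted_network(planted_bundle):
    net = network_from_edges(planted_bundle.true_edges)
    return annotate_network(net, planted_bundle.true_states)


def random_colored_digraph(n, p, rng, states=4):
    """Erdos-Renyi digraph with uniform random 4-state colors."""
    labels = [f"S{i}" for i in range(states)]
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u, v in itertools.permutations(range(n), 2):
        if rng.random() < p:
            g.add_edge(u, v)
    for node in g.nodes:
        g.nodes[node]["broad_state"] = labels[rng.integers(0, states)]
    return g
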