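import random

import pytest

from multiloal import (
    GeneratorParams,
    MultilayerNetwork,
    NodeRef,
    generate_multilayer,
)


@pytest.fixture
def tiny_net() -> MultilayerNetwork:
    """Two layers, a path a-b-c in L1, edge a-b in L2, one inter edge."""
    net = MultilayerNetwork(name="tiny")
    net.add_intra_edge("L1", "a", "b")
    net.add_intra_edge("L1", "b", "c")
    net.add_intra_edge("L2", "a", "b")
    net.add_node("L2", "c")
    net.add_inter_edge(NodeRef("L1", "a"), NodeRef("L2", "a"))
    return net


@pytest.fixture
def n1_net() -> MultilayerNetwork:
    """A benchmark-shaped network: 2 layers, 30 nodes, 90 edges."""
    return generate_multilayer(GeneratorParams(30, 2, 90, 0.2, seed=7), "N1")


def random_layer_graph(rng: random.Random, n_nodes: int, p: float):
    """Random edge set over node ids x1..xn (Erdős–Rényi G(n, p))."""
    ids = [f"x{i}" for i in range(1, n_nodes + 1)]
    edges = [
        (u, v)
        for i, u in enumerate(ids)
        for v in ids[i + 1 :]
        if rng.random() < p
    ]
    return ids, edges
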