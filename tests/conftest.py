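import numpy as np
import pytest

from leadnet.network import InteractionNetwork


@pytest.fixture
def triangle() -> InteractionNetwork:
    """A-B 0.9, A-C 0.95, B-C 0.99: the hand-checked WNL/TIS fixture."""
    return InteractionNetwork([("A", "B", 0.9), ("A", "C", 0.95), ("B", "C", 0.99)])


@pytest.fixture
def banded_net() -> InteractionNetwork:
    """Five edges spanning the confidence band boundaries."""
    return InteractionNetwork([
        ("A", "B", 0.85), ("A", "C", 0.90), ("B", "C", 0.95),
        ("C", "D", 0.99), ("D", "E", 0.995),
    ])


def random_network(rng: np.random.Generator, max_nodes: int = 50) -> InteractionNetwork:
    """Erdos-Renyi-ish random network with uniform (0, 1] scores."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"N{i}" for i in range(n)]
    net = InteractionNetwork(nodes=names)
    p = rng.uniform(0.05, 0.4)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(names[i], names[j], float(rng.uniform(1e-6, 1.0)))
    return net
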