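import numpy as np
import pytest

from pathmult import Graph, ModelConfig, generate, giant_connected_component, make_fixture
from pathmult.graph import is_connected


@pytest.fixture
def fig1_union():
    return make_fixture("fig1_union")


def random_connected_graph(rng: np.random.Generator, n_max: int = 60) -> Graph:
    """A random connected ER graph, redrawn until connected."""
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(1.8, 4.0)) / n  # around the connectivity threshold
    while True:
        g = generate(ModelConfig(model="er", n=n, p=min(p, 1.0),
                                 seed=int(rng.integers(2**31))))
        if is_connected(g):
            return g
        p = min(1.0, p * 1.3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240605)
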