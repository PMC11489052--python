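import numpy as np
import pytest

from cohortpbn.model_io import BooleanNetwork, parse_bnet
from cohortpbn.synthetic_data import gen_toy_networks


@pytest.fixture
def negation_loop() -> BooleanNetwork:
    """A, !B / B, A — two-node negative feedback loop."""
    return parse_bnet("targets, factors\nA, !B\nB, A\n")


@pytest.fixture
def oscillator() -> BooleanNetwork:
    return gen_toy_networks("oscillator")


@pytest.fixture
def chain3() -> BooleanNetwork:
    return gen_toy_networks("chain3")


@pytest.fixture
def prkn_shape() -> BooleanNetwork:
    return gen_toy_networks("prkn_shape")


def random_network(seed: int, n_nodes: int = 6) -> BooleanNetwork:
    return gen_toy_networks("random", seed=seed, n_nodes=n_nodes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
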