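import numpy as np
import pytest

from mechbool.fixtures import (build_emt_switch, feedback_ring,
                               generate_random_network, toggle_switch)


@pytest.fixture(scope="session")
def emt_switch():
    return build_emt_switch()


@pytest.fixture(scope="session")
def toggle():
    return toggle_switch()


@pytest.fixture(scope="session")
def ring3():
    return feedback_ring(3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instances(count, seed=42, max_noninput=12, max_inputs=3,
                     max_in_degree=3):
    """Seeded stream of random test networks with bounded sub-space size."""
    meta = np.random.default_rng(seed)
    for i in range(count):
        n_inputs = int(meta.integers(0, max_inputs + 1))
        n_non = int(meta.integers(4, max_noninput + 1))
        bias = float(meta.uniform(0.3, 0.7))
        yield generate_random_network(n_non + n_inputs, n_inputs,
                                      max_in_degree, bias,
                                      seed=int(meta.integers(0, 2 ** 31)))
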