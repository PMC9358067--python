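import numpy as np
import pytest

from memtop.decoder import build_state_machine
from memtop.synthetic_data import GeneratorConfig


@pytest.fixture(scope="session")
def sm():
    return build_state_machine()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(seed=42)


def random_probs(rng, L):
    """Row-stochastic L x 5 matrix."""
    p = rng.random((L, 5))
    return p / p.sum(axis=1, keepdims=True)
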