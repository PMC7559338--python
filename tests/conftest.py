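import numpy as np
import pytest

from dlgrn.simulate import SimulationScenario, generate_expression, generate_network


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_planted():
    """A small noise-free planted system: 30 samples, 200 genes, 8 regulators."""
    adj = generate_network(200, 8, 3.0, (2, 4), random_state=7)
    Y, profiles, truth = generate_expression(adj, 30, np.inf, random_state=8)
    return Y, profiles, truth


@pytest.fixture(scope="session")
def noisy_planted():
    """A moderate-noise planted system used by inference-level tests."""
    adj = generate_network(300, 12, 3.0, (2, 5), random_state=17)
    Y, profiles, truth = generate_expression(adj, 40, 20.0, random_state=18)
    return Y, profiles, truth


@pytest.fixture
def random_dictionary(rng):
    D = rng.standard_normal((6, 8))
    return D / np.linalg.norm(D, axis=0)
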