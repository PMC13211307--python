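import numpy as np
import pytest

from ecofeas import EnergeticNetwork, example_two_population_network


@pytest.fixture(scope="session")
def two_pop():
    """The packaged two-population worked example network."""
    return example_two_population_network()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def random_dissipative_3():
    """A fixed, hand-checkable 3-population dissipative network."""
    sigma = np.array([
        [2.0, 0.6, -0.3],
        [0.4, 1.8, 0.5],
        [0.5, -0.2, 2.2],
    ])
    return EnergeticNetwork(sigma, d=[0.8, 1.1, 0.9], N0=[1.0, 0.9, 1.3])
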