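import numpy as np
import pytest

from grnpio import (
    BenchmarkSpec,
    dataset1_network,
    dataset2_network,
    generate_profile,
)


@pytest.fixture(scope="session")
def ds1_network():
    return dataset1_network()


@pytest.fixture(scope="session")
def ds2_network():
    return dataset2_network()


@pytest.fixture(scope="session")
def ds1_profile(ds1_network):
    return generate_profile(BenchmarkSpec("dataset1"), ds1_network)


@pytest.fixture(scope="session")
def ds2_profile(ds2_network):
    return generate_profile(BenchmarkSpec("dataset2"), ds2_network)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20141203)
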