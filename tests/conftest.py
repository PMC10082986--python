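import numpy as np
import pytest

from isoga.simulate import fixture_suite


@pytest.fixture(scope="session")
def suite():
    return fixture_suite()


@pytest.fixture(scope="session")
def collinear4(suite):
    return suite["collinear4"]


@pytest.fixture(scope="session")
def twoclusters(suite):
    return suite["twoclusters"]


@pytest.fixture(scope="session")
def swissroll200(suite):
    return suite["swissroll200"]


@pytest.fixture(scope="session")
def separable(suite):
    return suite["separable"]


@pytest.fixture(scope="session")
def planted300(suite):
    return suite["planted300"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
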