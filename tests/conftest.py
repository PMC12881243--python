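import numpy as np
import pytest

from casim import Network, preset


@pytest.fixture(scope="session")
def felix_net():
    """One wired felix-mode network shared by read-only tests."""
    return Network.build(preset("felix"), seed=11)


@pytest.fixture()
def fresh_felix_net():
    """A private network for tests that mutate weights or state."""
    return Network.build(preset("felix"), seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
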