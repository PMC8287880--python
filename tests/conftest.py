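import numpy as np
import pytest

from sigvsim import CircuitParameters, VariantSpec, build_network


@pytest.fixture(scope="session")
def params():
    """The published rate-constant set of the circuit."""
    return CircuitParameters()


@pytest.fixture(scope="session")
def wt_network(params):
    return build_network(params, VariantSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)
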