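import numpy as np
import pytest

from eicorr import make_network


@pytest.fixture(scope="session")
def asyn_net():
    """One heterogeneous asynchronous-regime network realization."""
    return make_network("asynchronous", heterogeneous=True, rng_seed=7)


@pytest.fixture(scope="session")
def sa_net():
    """One heterogeneous strong-asynchronous network realization."""
    return make_network("strong_asynchronous", heterogeneous=True, rng_seed=7)


@pytest.fixture(scope="session")
def asyn_lr(asyn_net):
    """Linear-response solution of the asynchronous network (shared across
    tests; ~10 s to build)."""
    from eicorr import NetworkLinearResponse
    return NetworkLinearResponse(asyn_net)


@pytest.fixture(scope="session")
def sa_lr(sa_net):
    from eicorr import NetworkLinearResponse
    return NetworkLinearResponse(sa_net)
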