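import numpy as np
import pytest

from lcfad import (
    NS1,
    NS2,
    BatchConfig,
    InoculumSpec,
    ModelParameters,
    initial_state,
    simulate_batch,
)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def inoculum():
    return InoculumSpec()


@pytest.fixture(scope="session")
def ns1_reference_state(inoculum):
    """Initial state of the high-lipid bottle at I/S = 1.0, no calcium."""
    return initial_state(NS1, inoculum, BatchConfig(is_ratio=1.0))


@pytest.fixture(scope="session")
def ns1_trajectory(inoculum):
    """A 20-day reference simulation reused across read-only tests."""
    return simulate_batch(NS1, inoculum, BatchConfig(is_ratio=1.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
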