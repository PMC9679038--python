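import pytest
from hypothesis import HealthCheck, settings

# Deterministic property tests: derandomised, no deadline (CI boxes vary).
settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from hbgsh.composition import RbcComposition
from hbgsh.linkage import GshLinkage, default_mwc_params
from hbgsh.itc import ItcProtocol


@pytest.fixture(scope="session")
def comp():
    return RbcComposition()


@pytest.fixture(scope="session")
def mwc():
    """Two-state parameters calibrated to P50 = 26 mmHg."""
    return default_mwc_params()


@pytest.fixture(scope="session")
def linkage():
    return GshLinkage()


@pytest.fixture(scope="session")
def protocol():
    return ItcProtocol()
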