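import logging

import pytest
from hypothesis import HealthCheck, settings

# Deterministic property testing: one fixed profile for every run.
settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    """Silence expected exclusion warnings unless a test inspects them."""
    logging.getLogger("bxmap.finemap").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def fine_panel():
    import bxmap

    return bxmap.make_fixture("fine374", seed=1)


@pytest.fixture(scope="session")
def scan_panel():
    import bxmap

    return bxmap.make_fixture("scan103", seed=1)
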