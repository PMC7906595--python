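import pytest
from hypothesis import HealthCheck, settings

import fermkin as fk

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref():
    """Literature-calibrated reference bundle."""
    return fk.reference_dataset()


@pytest.fixture(scope="session")
def params(ref):
    """Calibrated inhibited-model parameters (exponential family)."""
    return ref.params


@pytest.fixture(scope="session")
def yields(ref):
    return ref.yields


@pytest.fixture
def initial_100():
    """Standard inoculum in 100 g/L glucose."""
    return fk.BatchState(t=0.0, X=1.0, S=100.0, P=0.0, Z=0.0)
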