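import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def reference_template():
    from cipoc.fixtures import make_reference_template
    return make_reference_template()


@pytest.fixture
def reference_cgm():
    from cipoc.fixtures import make_reference_cgm
    return make_reference_cgm()


@pytest.fixture
def toy_backend():
    from cipoc.chem import ToyForceField
    return ToyForceField()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
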