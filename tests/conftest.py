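import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ngbkin.synthetic_data import get_fixture

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def wt_fixture():
    return get_fixture("wt_like")


@pytest.fixture(scope="session")
def cdless_fixture():
    return get_fixture("cdless_like")


@pytest.fixture(scope="session")
def nu3_cdless_fixture():
    return get_fixture("nu3_cdless")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
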