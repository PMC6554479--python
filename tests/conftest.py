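import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "centwave",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("centwave")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_scenario():
    from centwave import CentromereScenario

    return CentromereScenario()


@pytest.fixture
def default_ld():
    from centwave import LDScenario

    return LDScenario()
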