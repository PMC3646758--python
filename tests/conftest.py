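import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rt_library():
    from lipidphys import default_rt_library

    return default_rt_library()


@pytest.fixture
def rng():
    return np.random.default_rng(20130507)
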