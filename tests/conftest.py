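import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def geometry():
    from stereomotion import ViewingGeometry

    return ViewingGeometry(i=6.5, D=57.0)
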