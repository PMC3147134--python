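import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def jaszczak_low_contrast():
    """Rasterized multi-sphere phantom at the lowest sphere/background level."""
    from maaspect.phantoms import jaszczak_spec, rasterize

    spec = jaszczak_spec("18.5 MBq/sphere")
    image, masks = rasterize(spec)
    return spec, image, masks


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
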