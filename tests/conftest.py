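import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def materials():
    from fidmark.materials import default_materials

    return default_materials()


@pytest.fixture(scope="session")
def study_phantom():
    from fidmark.phantom import default_study_phantom

    return default_study_phantom()


@pytest.fixture()
def flat_image():
    """64x64 constant image, 0.5 mm pixels."""
    from fidmark.image import Image2D

    return Image2D(pixels=np.full((64, 64), 7.0), spacing=(0.5, 0.5))
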