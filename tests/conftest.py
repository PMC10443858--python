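import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eye3d

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_phantom():
    """61-px phantom section plus ground-truth masks (session-wide, read-only)."""
    return eye3d.make_phantom_section(eye3d.PhantomSpec.default(61), seed=7)


@pytest.fixture(scope="session")
def small_volume(small_phantom):
    """The 61-px phantom rotated at the reference 0.2 deg step."""
    img, _ = small_phantom
    return eye3d.rotate_section(img)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_section(rng, h=9, w=11):
    """Small random RGB section (collision-heavy voxelizer input)."""
    return eye3d.SectionImage(rng.integers(0, 255, (h, w, 3)).astype(np.uint8))
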