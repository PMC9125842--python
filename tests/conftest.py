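import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wmcvol.phantom import PhantomSpec, generate_phantom
from wmcvol.types import BinaryMask, VolumeImage

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def compact_phantom():
    """One small noise-free phantom shared across tests (read-only)."""
    spec = PhantomSpec.compact(seed=7)
    image, truth = generate_phantom(spec)
    return spec, image, truth


@pytest.fixture()
def flat_image():
    """Tiny two-tissue image: dark slab (value 10) and bright slab (value 90)."""
    vals = np.full((12, 12, 12), 10.0)
    vals[:, :, 6:] = 90.0
    img = VolumeImage(vals)
    brain = BinaryMask(np.ones(vals.shape, dtype=bool))
    return img, brain
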