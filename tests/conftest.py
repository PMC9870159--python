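import numpy as np
import pytest

from cellwarp import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """48-frame 96x96 smooth-random phantom shared across read-only tests."""
    return generate_phantom(
        PhantomSpec(image_size=96, n_frames=48, warp_amplitude=2.5, seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disk_mask():
    """Centered disk in a 64x64 frame."""
    rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    return np.hypot(rr - 31.5, cc - 31.5) < 20
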