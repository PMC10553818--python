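import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def rasterize_disk(shape, center_rc, radius):
    """Independent analytic disk rasterization: pixel in disk iff its
    center is within ``radius`` of ``center_rc``."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius**2


@pytest.fixture
def disk_frame():
    """Noiseless disk of intensity 510 (background 10) for segmentation tests."""
    shape = (200, 200)
    frame = np.full(shape, 10.0)
    mask = rasterize_disk(shape, (100, 100), 40)
    frame[mask] += 500.0
    return frame, mask
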