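import numpy as np
import pytest

from microglia_morph import (
    SegmentationParams,
    generate_field,
    segment_projection,
)


@pytest.fixture(scope="session")
def default_field():
    """Default 20-cell synthetic field, mixed resting/activated, seed 0."""
    return generate_field(seed=0)


@pytest.fixture(scope="session")
def default_records(default_field):
    return segment_projection(default_field.projection())


@pytest.fixture(scope="session")
def low_noise_field():
    """Nearly noise-free field: masks are clean, shape regimes undistorted."""
    return generate_field(seed=0, noise_sigma=1.0, illumination_amp=0.0)


@pytest.fixture(scope="session")
def low_noise_records(low_noise_field):
    return segment_projection(low_noise_field.projection())


@pytest.fixture
def params():
    return SegmentationParams()


def rasterized_disk(radius_px: int) -> np.ndarray:
    side = 2 * radius_px + 5
    rr, cc = np.mgrid[0:side, 0:side]
    c = side // 2
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius_px**2
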