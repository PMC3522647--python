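import numpy as np
import pytest

from cardiot2star import (ImageGeometry, make_heart_phantom,
                          make_medium_t2star_phantom)


@pytest.fixture(scope="session")
def small_geometry():
    return ImageGeometry(matrix=(64, 64), fov_mm=(72.0, 72.0), slice_thickness_mm=4.0)


@pytest.fixture(scope="session")
def medium_small(small_geometry):
    """Medium-T2* cylinder scaled to a 64x64 grid (40 mm diameter)."""
    return make_medium_t2star_phantom(geometry=small_geometry, diameter_mm=40.0)


@pytest.fixture(scope="session")
def heart_phantom():
    """Default dynamic heart phantom (25 phases, 128x128)."""
    return make_heart_phantom()


@pytest.fixture(scope="session")
def heart_roi(heart_phantom):
    y, x = heart_phantom.geometry.coordinate_grids()
    return np.hypot(y, x) <= 35.0
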