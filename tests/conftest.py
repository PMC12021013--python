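import numpy as np
import pytest

from tiettd import OpticalConfig, RoiSet


@pytest.fixture
def config():
    """Blue-illumination acquisition with a dry objective, planes at +/-0.5 um."""
    return OpticalConfig(
        wavelength=0.486,
        n_imm=1.0,
        n_medium=1.335,
        defocus_separation=1.0,
        pixel_size=0.3,
        dark_level=0.0,
    )


def disk_labels(shape, radius_um, pixel_size, label=1, center=None):
    """Label image with a single centered disk ROI; everything else background."""
    ny, nx = shape
    if center is None:
        center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    yy, xx = np.indices(shape)
    r = np.hypot(yy - center[0], xx - center[1]) * pixel_size
    return RoiSet(np.where(r <= radius_um, label, 0))


@pytest.fixture
def make_disk_labels():
    return disk_labels
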