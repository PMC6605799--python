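import numpy as np
import pytest

from exoquant import CellROI, Image2D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def full_roi():
    """Polygon covering an entire 64x64 frame (all pixel centers inside)."""
    return CellROI([[-0.5, -0.5], [-0.5, 63.5], [63.5, 63.5], [63.5, -0.5]])


def gaussian_spot_image(shape, centers, amplitude=100.0, sigma=2.0, background=0.0):
    """Noiseless sum of isotropic Gaussian peaks — analytic ground truth."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, float(background))
    for r0, c0 in centers:
        img += amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
    return img


def disk_image(shape, centers, radius=4, amplitude=100.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape)
    for r0, c0 in centers:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = amplitude
    return img


@pytest.fixture
def spot_image_factory():
    def build(shape, centers, **kwargs):
        return Image2D(gaussian_spot_image(shape, centers, **kwargs), pixel_size=0.1)

    return build
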