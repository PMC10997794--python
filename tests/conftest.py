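import numpy as np
import pytest

from dsbquant import DetectionParams, Focus, Image2D, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_params():
    return DetectionParams()


@pytest.fixture
def small_config():
    """A light-weight simulation config for fast unit tests."""
    return SimConfig(
        image_shape=(256, 256),
        n_axes=8,
        axis_length_range=(6.0, 10.0),
        n_cofoci=25,
        n_single_ch1=8,
        n_single_ch2=8,
        n_large_foci=1,
        seed=99,
    )


def make_focus(pixels, focus_id=0, channel="MEI4", pixel_size=0.1):
    return Focus(focus_id=focus_id, channel=channel,
                 pixels=np.asarray(pixels), pixel_size=pixel_size)


def gaussian_spot(shape, center, sigma, amplitude):
    """Analytic Gaussian spot image used as a clean detection target."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(
        -((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma ** 2))


@pytest.fixture
def spot_image():
    data = gaussian_spot((64, 64), (32, 32), 1.6, 100.0)
    return Image2D(data, 0.1)
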