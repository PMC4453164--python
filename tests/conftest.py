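import numpy as np
import pytest

from spindlescreen.image_pipeline import PipelineParams


@pytest.fixture
def params():
    return PipelineParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def disc_mask(shape, center, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def gaussian_spot(shape, center, sigma, amplitude):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-(((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                                / (2.0 * sigma**2)))


@pytest.fixture
def spot_patch():
    """Factory: a tubulin-like patch with Gaussian foci inside a disc mask."""

    def build(foci, shape=(64, 64), radius=26, background=24.0, sigma=2.5,
              amplitude=160.0, noise_sd=0.0, seed=0):
        img = np.full(shape, background, dtype=float)
        center = (shape[0] // 2, shape[1] // 2)
        for pos in foci:
            img += gaussian_spot(shape, pos, sigma, amplitude)
        if noise_sd > 0:
            img += np.random.default_rng(seed).normal(0, noise_sd, shape)
        return img, disc_mask(shape, center, radius)

    return build
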