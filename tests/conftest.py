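import numpy as np
import pytest

import polysumo as ps


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_disk(shape, center, radius, value=1.0):
    """Filled disk on a zero background."""
    img = np.zeros(shape, dtype=np.float64)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2] = value
    return img


def add_gaussian_spot(img, r, c, sigma, peak):
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    img += peak * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * sigma**2))
    return img


@pytest.fixture(scope="session")
def small_scene():
    """One small easy-regime scene shared by read-only tests."""
    spec = ps.SceneSpec(
        field_shape=(256, 256), n_nuclei=2, puncta_per_cell_lambda=6, seed=77
    )
    fld, truth = ps.generate_scene(spec)
    return spec, fld, truth
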