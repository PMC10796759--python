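import numpy as np
import pytest

from drillct.core import CTVolume
from drillct.phantom import PhantomConfig, carve_canal, make_phantom

PHANTOM_SHAPE = (72, 72, 72)
PHANTOM_SPACING = 0.5


@pytest.fixture(scope="session")
def aligned_phantom():
    """Pre volume + truth with zero misalignment (registration-free tests)."""
    cfg = PhantomConfig(max_rotation_deg=0.0, max_translation_mm=0.0)
    pre, truth = make_phantom(PHANTOM_SHAPE, PHANTOM_SPACING, seed=11, config=cfg)
    return pre, truth


@pytest.fixture(scope="session")
def aligned_pair_volumes(aligned_phantom):
    """(pre, post, truth) with the canal carved, no misalignment."""
    pre, truth = aligned_phantom
    return pre, carve_canal(pre, truth), truth


@pytest.fixture(scope="session")
def noisefree_phantom():
    """Fully deterministic phantom: no texture, no canal or force noise."""
    cfg = PhantomConfig(
        noise_sd_hu=0.0,
        air_noise_sd_hu=0.0,
        force_noise_sd_n=0.0,
        max_rotation_deg=0.0,
        max_translation_mm=0.0,
    )
    pre, truth = make_phantom(PHANTOM_SHAPE, PHANTOM_SPACING, seed=5, config=cfg)
    return pre, truth


@pytest.fixture()
def smooth_volume():
    """A smooth analytic HU field for interpolation-error measurements."""
    n = 48
    idx = np.indices((n, n, n), dtype=np.float64)
    x, y, z = (i * 0.5 for i in idx)
    data = 400 * np.sin(x / 4.0) * np.cos(y / 5.0) + 300 * np.sin(z / 6.0)
    return CTVolume(data, (0.5, 0.5, 0.5), (0.0, 0.0, 0.0))
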