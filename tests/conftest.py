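import numpy as np
import pytest
from hypothesis import settings

from olfbold.paradigm import build_paradigm
from olfbold.phantom import RoiSpec, default_config, null_config

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schedule():
    """The standard olfactory paradigm: 60 s off + 3 x (60 s on + 120 s off)."""
    return build_paradigm(2.0, 60.0, 3, 60.0, 120.0, 1.0, 2.0)


def small_layout():
    """Three compact ROIs that fit a 16x16x10 grid."""
    return (
        RoiSpec("bulb_like", (8, 3, 4), (4, 2, 2), "cuboid", "positive",
                amplitude=0.022, rho=0.2),
        RoiSpec("cortex_like", (5, 10, 5), (3, 3, 3), "cuboid", "positive",
                amplitude=0.012),
        RoiSpec("neg_like", (11, 10, 5), (3, 3, 3), "cuboid", "negative",
                amplitude=0.005),
    )


@pytest.fixture()
def small_cfg():
    """Small-grid config with noise, for fast end-to-end tests."""
    return default_config(grid_shape=(16, 16, 10), roi_layout=small_layout())


@pytest.fixture()
def small_clean_cfg():
    """Small-grid noiseless config (deterministic signal only)."""
    return default_config(
        grid_shape=(16, 16, 10), roi_layout=small_layout(),
        sigma_thermal=0.0, drift_amp=0.0, resp_amp=0.0,
    )


@pytest.fixture()
def small_null_cfg():
    """Small-grid activation-free config."""
    return null_config(grid_shape=(16, 16, 10), roi_layout=small_layout())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
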