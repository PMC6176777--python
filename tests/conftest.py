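import numpy as np
import pytest

from canophen.geo_io import BAND_NAMES, BandStack, GridGeometry
from canophen.scene_sim import SceneConfig, simulate_scene
from canophen.traits import extract_scene_traits


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """A reduced 4 lines x 2 treatments x 2 reps field (16 plots)."""
    return SceneConfig(n_lines=4, n_treatments=2, n_reps=2, seed=11)


@pytest.fixture(scope="session")
def small_scene(small_config):
    """A fully rendered default-parameter scene, shadows cast."""
    return simulate_scene(small_config)


@pytest.fixture(scope="session")
def small_scene_traits(small_scene):
    return extract_scene_traits(small_scene)


@pytest.fixture(scope="session")
def noiseless_config() -> SceneConfig:
    """All noise off and equal plant heights: exact trait recovery expected."""
    from canophen.scene_sim import NoiseParams

    return SceneConfig(
        n_lines=3, n_treatments=2, n_reps=1, seed=5,
        noise=NoiseParams(biomass_log_sd=0.0, reflectance_sd=0.0, height_sd_m=0.0),
        height_range_cm=(400.0, 400.0),
    )


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_config):
    return simulate_scene(noiseless_config)


def make_stack(arrays: dict, gsd: float = 1.0) -> BandStack:
    """Build a BandStack from per-band constant values or arrays."""
    shape = None
    for v in arrays.values():
        if np.ndim(v) == 2:
            shape = np.shape(v)
    if shape is None:
        shape = (4, 4)
    data = np.stack(
        [np.broadcast_to(np.asarray(arrays[name], float), shape) for name in BAND_NAMES]
    ).astype(float)
    grid = GridGeometry(0.0, shape[0] * gsd, gsd, gsd, shape[0], shape[1])
    return BandStack(data, grid)
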