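import numpy as np
import pytest

from restmvpa.preproc import BandSpec
from restmvpa.synthgen import EffectSpec, SimulationConfig, generate_cohort, make_masks


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Small, fast cohort: 12^3 grid, 60 volumes, 4 per group."""
    return SimulationConfig(grid_shape=(12, 12, 12), n_volumes=60, n_per_group=4, seed=7)


@pytest.fixture(scope="session")
def tiny_masks(tiny_config):
    return make_masks(tiny_config.grid_shape)


@pytest.fixture(scope="session")
def tiny_null_cohort(tiny_config):
    return generate_cohort(tiny_config, [])


@pytest.fixture(scope="session")
def tiny_effect_cohort(tiny_config):
    effects = [EffectSpec(kind="amplitude", center_voxel=(6, 6, 9),
                          radius_voxels=2.5, effect_size=2.5)]
    cohort, masks = generate_cohort(tiny_config, effects)
    return cohort, masks, effects


@pytest.fixture
def band_2s() -> BandSpec:
    return BandSpec(low_hz=0.01, high_hz=0.08, tr_s=2.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
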