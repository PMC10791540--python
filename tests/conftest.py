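import numpy as np
import pytest

from ctrecur import (PipelineConfig, VariogramConfig, VolumeSpec, gen_volume)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_volume_spec():
    """Desk-scale volume: 30 slices of 48x48, bone from row 13 down."""
    return VolumeSpec(n_slices=30, height=48, width=48, bone_row_start=13,
                      sill=0.004, corr_range=2.0, background_level=0.1, seed=7)


@pytest.fixture(scope="session")
def small_volume(small_volume_spec):
    return gen_volume(small_volume_spec)


@pytest.fixture(scope="session")
def small_vario_config():
    return VariogramConfig(h=1, intensity_min=0.5, row_min=13, n_slices=30)


@pytest.fixture(scope="session")
def small_pipeline_config(small_vario_config):
    return PipelineConfig(variogram=small_vario_config, seed=11)
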