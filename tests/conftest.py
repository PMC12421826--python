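import numpy as np
import pytest

from ecitools import (
    DielectricParams,
    SensorGeometry,
    draw_channel_offsets,
    make_colony_phantom,
)


@pytest.fixture
def small_geometry() -> SensorGeometry:
    """Reduced grid (same aspect ratio and 8-channel layout as the sensor)."""
    return SensorGeometry(n_rows=64, n_cols=128)


@pytest.fixture
def full_geometry() -> SensorGeometry:
    return SensorGeometry()


@pytest.fixture
def noiseless_params() -> DielectricParams:
    return DielectricParams(noise_sd_fF=0.0)


@pytest.fixture
def default_params() -> DielectricParams:
    return DielectricParams()


@pytest.fixture
def offset_params() -> DielectricParams:
    offs = draw_channel_offsets(np.random.default_rng(42), 8)
    return DielectricParams(noise_sd_fF=1.0, channel_offsets_fF=offs)


@pytest.fixture
def small_phantom(small_geometry):
    return make_colony_phantom(
        small_geometry, n_blobs=4, max_thickness_um=33.2, smoothness_px=10, seed=3
    )
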