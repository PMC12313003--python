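"""Shared fixtures: small noiseless phantoms and default ground truths."""

import numpy as np
import pytest

from gliaphys.synth import (
    ChlorideDynamicsParams,
    EphysGroundTruth,
    OpticsNoiseParams,
    SceneConfig,
    VolumeDynamicsParams,
    build_astrocyte_phantom,
    render_timeseries,
    simulate_chloride_timecourse,
    simulate_volume_timecourse,
)

SMALL_SCENE = SceneConfig(
    shape=(8, 32, 32),
    pixel_size=0.4,
    z_step=2.0,
    soma_radius=2.5,
    process_inner_radius=3.0,
    process_outer_radius=5.5,
)


@pytest.fixture
def default_volume_params() -> VolumeDynamicsParams:
    return VolumeDynamicsParams()


@pytest.fixture
def volume_series(default_volume_params) -> np.ndarray:
    return simulate_volume_timecourse(default_volume_params)


@pytest.fixture
def chloride_and_ratio(volume_series):
    return simulate_chloride_timecourse(volume_series, ChlorideDynamicsParams())


@pytest.fixture
def noiseless_optics() -> OpticsNoiseParams:
    return OpticsNoiseParams(photon_noise=False, read_noise_sd=0.0)


@pytest.fixture
def phantom_scene():
    return build_astrocyte_phantom(SceneConfig(), seed=7)


@pytest.fixture
def small_scene():
    return build_astrocyte_phantom(SMALL_SCENE, seed=7)


@pytest.fixture
def noiseless_series(small_scene, volume_series, chloride_and_ratio, noiseless_optics):
    _, ratio = chloride_and_ratio
    return render_timeseries(
        small_scene, volume_series, ratio, noiseless_optics, seed=11
    )


@pytest.fixture
def default_ephys_gt() -> EphysGroundTruth:
    return EphysGroundTruth()
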