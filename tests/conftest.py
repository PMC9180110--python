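import numpy as np
import pytest

from opticpath import VoxelGrid, compartments, phantom


@pytest.fixture(scope="session")
def small_grid() -> VoxelGrid:
    # AP extent 96 mm keeps the full 68 mm tract span at a quarter the voxels
    return VoxelGrid(dims=(48, 48, 32), voxel_size=2.0, ap_axis=1)


@pytest.fixture(scope="session")
def truth(small_grid):
    return phantom.make_geometry(small_grid, seed=0)


@pytest.fixture(scope="session")
def landmarks(truth):
    return phantom.make_landmarks(truth)


@pytest.fixture(scope="session")
def control_vols(truth):
    return phantom.simulate_volumes(truth, group="control", noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def control_fractions(control_vols):
    return compartments.compute_fractions(control_vols.wm, control_vols.gm, control_vols.csf)


@pytest.fixture(scope="session")
def left_eye_density(truth):
    from opticpath import masking

    sls = phantom.simulate_streamlines(truth, 400, jitter_sd=1.0, seed=21)
    return masking.density_map(sls.subset(side="left"), truth.grid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
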