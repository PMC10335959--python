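import numpy as np
import pytest

import gradmap as gm


@pytest.fixture(scope="session")
def ref_dataset():
    """The reference synthetic dataset (default generator conditions)."""
    return gm.generate_dataset(gm.SyntheticConfig())


@pytest.fixture(scope="session")
def ref_results(ref_dataset):
    return gm.GradientModel.from_dataset(ref_dataset).fit()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free dataset with 4 networks and two planted ramps."""
    return gm.generate_dataset(gm.SyntheticConfig(noise_sd=0.0))


@pytest.fixture(scope="session")
def noiseless_results(noiseless_dataset):
    return gm.GradientModel.from_dataset(noiseless_dataset).fit()


@pytest.fixture(scope="session")
def noiseless5_dataset():
    """Noise-free dataset with 5 networks (some never win a seed voxel)."""
    return gm.generate_dataset(gm.SyntheticConfig(noise_sd=0.0, n_networks=5))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast-to-analyze dataset for I/O and pipeline plumbing tests."""
    return gm.generate_dataset(
        gm.SyntheticConfig(grid_shape=(10, 10, 10), n_timepoints=60, n_subjects=2, seed=5)
    )


@pytest.fixture
def cube_map():
    """A deterministic smooth SeedMap on a small grid."""
    coords = np.argwhere(np.ones((5, 5, 4), dtype=bool)) * 3.0
    vals = coords @ np.array([0.2, 1.0, 0.5]) + 0.01 * np.sin(np.arange(coords.shape[0]))
    hemi = np.where(coords[:, 0] < 7.5, "L", "R")
    return gm.SeedMap(vals, coords, hemi)
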