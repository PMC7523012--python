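import numpy as np
import pytest
from hypothesis import settings

from dwma import PhantomSpec, PipelineConfig, make_atlas, make_phantom, quantify_volume
from dwma.synthdata import cs_lesion_blob

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

SMALL_GRID = (64, 64, 64)


@pytest.fixture(scope="session")
def small_atlas():
    return make_atlas(SMALL_GRID, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_atlas):
    """Default-noise 64^3 phantom with one 60-voxel CS lesion plus truth."""
    blob = cs_lesion_blob(small_atlas, n_voxels=60, x_fraction=0.28)
    spec = PhantomSpec(grid_shape=SMALL_GRID, dwma_blobs=[blob], seed=7)
    volume, truth = make_phantom(spec, small_atlas)
    return spec, volume, truth


@pytest.fixture(scope="session")
def small_pipeline(small_atlas, small_phantom):
    """Full pipeline artifacts for the small phantom (run once per session)."""
    _, volume, _ = small_phantom
    return quantify_volume(volume, small_atlas, PipelineConfig())


@pytest.fixture(scope="session")
def clean_atlas():
    """Unsmoothed (hard indicator) atlas for degenerate-geometry checks."""
    return make_atlas(SMALL_GRID, smoothing_mm=0.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
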