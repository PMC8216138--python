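import numpy as np
import pytest
from hypothesis import settings

from osteotwin.grid import BONE, MARROW, VoxelGrid

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def solid_cube():
    """6^3 all-bone grid at 14 um voxels."""
    return VoxelGrid(np.full((6, 6, 6), BONE, dtype=np.uint8), 0.014)


@pytest.fixture
def embedded_cube():
    """3^3 bone cube centered in a 7^3 marrow domain."""
    t = np.zeros((7, 7, 7), dtype=np.uint8)
    t[2:5, 2:5, 2:5] = BONE
    return VoxelGrid(t, 0.014)


@pytest.fixture(scope="session")
def small_structure():
    """Connected 32^3 trabecular structure shared across tests."""
    from osteotwin.synth import StructureSpec, generate_trabecular

    return generate_trabecular(StructureSpec(shape=(32, 32, 32), target_bv_tv=0.131, seed=3))


@pytest.fixture(scope="session")
def medium_structure():
    """64^3 trabecular structure at the reference bone volume fraction."""
    from osteotwin.synth import StructureSpec, generate_trabecular

    return generate_trabecular(StructureSpec(target_bv_tv=0.131, seed=7))
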