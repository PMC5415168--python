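import numpy as np
import pytest

from rootone import BinaryVolume, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def random_volume(rng):
    """Small random uint16 greyscale volume."""
    return Volume(rng.integers(0, 65536, size=(8, 12, 10), dtype=np.uint16), 27.0)


def make_binary(data, voxel_size_um=27.0):
    return BinaryVolume(np.asarray(data, dtype=bool), voxel_size_um)


@pytest.fixture
def y_skeleton_volume():
    """A Y of three straight arms meeting at one voxel.

    Vertical arm of 5 voxels down to the junction at (4, 4, 4), then two
    diagonal arms of 4 steps each.
    """
    lab = np.zeros((10, 9, 9), dtype=bool)
    lab[0:5, 4, 4] = True
    for i in range(1, 5):
        lab[4 + i, 4 + i, 4] = True
        lab[4 + i, 4 - i, 4] = True
    return make_binary(lab, voxel_size_um=27.0)
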