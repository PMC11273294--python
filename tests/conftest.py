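import numpy as np
import pytest

from nuctools import VoxelSpacing, make_tissue


ISO = VoxelSpacing(0.25, 0.25, 0.25)


@pytest.fixture(scope="session")
def small_tissue():
    """A 48³ tissue with two N/C layers and a few nucleus-free cells."""
    return make_tissue(
        shape=(48, 48, 48),
        n_cells=30,
        nc_targets={"L1": 0.30, "L3": 0.23},
        spacing=ISO,
        nucleus_free_fraction=0.1,
        seed=0,
    )


@pytest.fixture(scope="session")
def linkage_tissue():
    """The 100-cell reference tissue used for linkage-truth checks."""
    return make_tissue(
        shape=(64, 64, 64),
        n_cells=100,
        nc_targets=0.25,
        spacing=ISO,
        nucleus_free_fraction=0.05,
        seed=0,
    )


def random_labels(rng, shape, n_objects):
    """Random blobby instance labels: nearest-seed partition of a subset."""
    vol = np.zeros(shape, dtype=np.int32)
    if n_objects == 0:
        return vol
    pts = np.stack([rng.integers(0, s, n_objects) for s in shape], axis=1)
    grid = np.indices(shape).reshape(3, -1).T
    d = ((grid[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    lab = d.argmin(axis=1) + 1
    keep = d.min(axis=1) < (min(shape) / 3) ** 2
    vol.ravel()[keep] = lab[keep]
    return vol
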