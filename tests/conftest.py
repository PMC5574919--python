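import numpy as np
import pytest

import fociquant as fq
from fociquant.foci import FociImage


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_foci_image(rng, shape=(16, 16), density=0.3, dtype=np.uint16):
    """A random small FociImage: nonzero intensities on a random support."""
    support = rng.random(shape) < density
    grid = np.zeros(shape, dtype=dtype)
    grid[support] = rng.integers(1, 60000 if dtype == np.uint16 else 250, size=int(support.sum()))
    return FociImage(grid=grid, support=support)


@pytest.fixture()
def small_scene():
    """One deterministic sparse scene plus its processed pipeline output."""
    field, truth = fq.generate_scene(fq.sparse_spec(7))
    processed, qc = fq.process_field(field)
    return field, truth, processed, qc


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
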