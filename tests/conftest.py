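import logging

import numpy as np
import pytest

from batperm.core import BinaryMask, LesionSet
from batperm.segmentation import merge_clusters
from batperm.synthetic import GeneratorConfig

# ring-emptiness warnings are expected on small synthetic lesions
logging.getLogger("batperm").setLevel(logging.ERROR)
logging.getLogger("batperm.rings").setLevel(logging.ERROR)


def disc_mask(shape, center, radius_px):
    """Boolean disc: pixels within radius_px of center (pixel units)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius_px


def two_disc_mask(shape, radius_px, gap_px, row=None):
    """Two aligned discs whose digital boundary gap equals gap_px exactly."""
    row = shape[0] // 2 if row is None else row
    c1 = shape[1] // 2 - (gap_px + 2 * radius_px) // 2
    c2 = c1 + 2 * radius_px + gap_px
    return disc_mask(shape, (row, c1), radius_px) | disc_mask(shape, (row, c2), radius_px)


def lesions_from_mask(mask, pixel_size=1.0, max_gap=100.0) -> LesionSet:
    return merge_clusters(BinaryMask(mask, pixel_size), max_gap)


def random_blob(rng, shape=(64, 64), n_seeds=3, radius=(3, 9)):
    """Random multi-disc blob for geometry oracles."""
    m = np.zeros(shape, dtype=bool)
    for _ in range(n_seeds):
        r = rng.integers(radius[0], radius[1] + 1)
        cr = rng.integers(r + 1, shape[0] - r - 1)
        cc = rng.integers(r + 1, shape[1] - r - 1)
        m |= disc_mask(shape, (cr, cc), r)
    return m


@pytest.fixture
def noiseless_config():
    """Single clean circular lesion, no noise, no heterogeneity."""
    return GeneratorConfig(
        poisson_scale=0.0,
        read_noise_sd=0.0,
        heterogeneity_cv=0.0,
        shape_irregularity=0.0,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
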