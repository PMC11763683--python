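import numpy as np
import pytest

from dxaradiomics.features.quantise import QuantisedRoi
from dxaradiomics.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Twenty small annotated images (4 degraded), shared across tests."""
    spec = CohortSpec(n_patients=20, degraded_fraction=0.2,
                      image_height=120, image_width=112,
                      texture_separation=2.0, seed=11)
    return generate_cohort(spec)


def random_roi(rng, shape=(15, 15), ng=6, irregular=True):
    """A random quantised ROI with an (optionally) irregular mask."""
    mask = np.ones(shape, dtype=bool)
    if irregular:
        mask = rng.random(shape) > 0.25
        if not mask.any():
            mask[shape[0] // 2, shape[1] // 2] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    return QuantisedRoi(levels=levels, mask=mask, n_levels=ng)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
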