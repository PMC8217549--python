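import numpy as np
import pytest

from asradiomics import ImageVolume, PhantomConfig, RoiMask, generate_cohort
from asradiomics.features import DiscretisedRoi


@pytest.fixture(scope="session")
def small_cohort():
    """A 6+6-lesion cohort with default planted effects (session-cached)."""
    cfg = PhantomConfig(n_progressors=6, n_stable=6, seed=11)
    lesions, cohort = generate_cohort(cfg)
    return cfg, lesions, cohort


@pytest.fixture(scope="session")
def one_lesion(small_cohort):
    _, lesions, _ = small_cohort
    return lesions[0]


def random_roi(rng, shape=(6, 6, 6), n_levels=4, density=0.7) -> DiscretisedRoi:
    """Random small discretised ROI for counting-identity property tests."""
    mask = rng.random(shape) < density
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = np.where(mask, rng.integers(1, n_levels + 1, shape), 0).astype(np.int32)
    return DiscretisedRoi(levels, mask, n_levels)


def sphere_mask(radius_vox=5, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0)) -> RoiMask:
    centre = (np.asarray(shape) - 1) / 2
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
    return RoiMask(d2 <= radius_vox**2, spacing)


def random_volume(rng, mask: RoiMask) -> ImageVolume:
    return ImageVolume(rng.normal(100, 20, mask.data.shape), mask.spacing)
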