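import numpy as np
import pytest

from zbmorph import synthetic


@pytest.fixture(scope="session")
def atlas_and_image():
    return synthetic.make_atlas()


@pytest.fixture(scope="session")
def atlas(atlas_and_image):
    return atlas_and_image[0]


@pytest.fixture(scope="session")
def atlas_image(atlas_and_image):
    return atlas_and_image[1]


@pytest.fixture(scope="session")
def small_cohort(atlas_and_image):
    """A tiny crispant cohort (3 vs 3, implanted s=0.8) for fast tests."""
    atlas, image = atlas_and_image
    spec = synthetic.CohortSpec(
        group_sizes={"control": 3, "crispant": 3}, atrophy_scale=0.8, seed=11
    )
    samples, truth = synthetic.make_cohort(spec, atlas, image)
    return spec, samples, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
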