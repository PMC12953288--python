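import numpy as np
import pandas as pd
import pytest

from steatodia import CohortSpec, ImageSpec, add_grading_columns, generate_cohort, generate_image


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One calibrated synthetic cohort at the default n=355."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def graded_cohort(default_cohort) -> pd.DataFrame:
    return add_grading_columns(default_cohort)


@pytest.fixture(scope="session")
def droplet_image():
    """Synthetic section with 40 tiny / 15 small / 6 large non-overlapping droplets."""
    spec = ImageSpec(n_tiny=40, n_small=15, n_large=6, seed=3)
    image, truth, mask = generate_image(spec)
    return spec, image, truth, mask


@pytest.fixture(scope="session")
def empty_tissue_image():
    """Tissue-only section: no droplets requested."""
    spec = ImageSpec(seed=5)
    image, truth, mask = generate_image(spec)
    return spec, image, truth, mask


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
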