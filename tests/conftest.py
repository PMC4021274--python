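import numpy as np
import pytest

from boundedmi import MissingnessSpec, impose, make_dataset


@pytest.fixture(scope="session")
def severe_data():
    """Severely skewed standard-score dataset (n=714, bounds 0-12)."""
    return make_dataset(714, "standard_like", "standard", seed=20140426)


@pytest.fixture(scope="session")
def mild_data():
    """Mildly skewed Likert-score dataset (n=714, bounds 0-36)."""
    return make_dataset(714, "likert_like", "likert", seed=20140426)


@pytest.fixture(scope="session")
def mcar_mask(severe_data):
    return impose(severe_data, MissingnessSpec(), seed=7).mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
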