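import numpy as np
import pytest

from famap import make_cohort, make_phantom_anatomy


@pytest.fixture(scope="session")
def anatomy():
    """Small phantom anatomy shared across read-only tests."""
    return make_phantom_anatomy(shape=(16, 16, 16), n_parcels=4,
                                critical_fraction=0.1, seed=1)


@pytest.fixture(scope="session")
def strong_cohort(anatomy):
    """A 60-subject cohort with a strong planted effect (low score noise)."""
    return make_cohort(anatomy=anatomy, n_subjects=60, noise_sd=0.5, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
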