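import numpy as np
import pytest
from hypothesis import settings

import slidealign as sa

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stain_matrix():
    return sa.default_stain_matrix()


@pytest.fixture(scope="session")
def small_spec():
    """Small phantom: 1024 px canvas, l_low at the 512 level."""
    return sa.PhantomSpec(seed=21, canvas=(1024, 1024), n_glands=5,
                          gland_radius=(30.0, 60.0), angle_deg=7.0,
                          scale=1.06, shift_xy=(20.0, -14.0))


@pytest.fixture(scope="session")
def small_pair(small_spec):
    return sa.make_pair(small_spec)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise- and jitter-free variant for exactness checks."""
    return sa.PhantomSpec(seed=21, canvas=(1024, 1024), n_glands=5,
                          gland_radius=(30.0, 60.0), angle_deg=7.0,
                          scale=1.06, shift_xy=(20.0, -14.0), noise_std=0.0)


@pytest.fixture(scope="session")
def clean_pair(clean_spec):
    return sa.make_pair(clean_spec)


@pytest.fixture(scope="session")
def reg_spec():
    """Registration-grade phantom: 2048 px canvas, richer structure."""
    return sa.PhantomSpec(seed=5, canvas=(2048, 2048), n_glands=8,
                          gland_radius=(40.0, 90.0), angle_deg=-12.0,
                          scale=0.93, shift_xy=(35.0, -55.0))


@pytest.fixture(scope="session")
def reg_pair(reg_spec):
    return sa.make_pair(reg_spec)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test."""
    return np.random.default_rng(20260920)
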