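"""Shared fixtures: one full-design synthetic dataset, processed once."""

import numpy as np
import pytest

from liftsig.preprocess import process_dataset
from liftsig.synthgen import GenParams, generate_dataset, make_cohort


@pytest.fixture(scope="session")
def default_params():
    """Default generator settings: the 15 x 4 x 3 individuality-dominant design."""
    return GenParams(seed=7)


@pytest.fixture(scope="session")
def dataset(default_params):
    return generate_dataset(default_params)


@pytest.fixture(scope="session")
def processed_with_exclusions(dataset):
    return process_dataset(dataset)


@pytest.fixture(scope="session")
def processed(processed_with_exclusions):
    return processed_with_exclusions[0]


@pytest.fixture(scope="session")
def small_processed():
    """A reduced design (6 participants x 4 conditions x 2 trials) for fast tests."""
    params = GenParams(seed=11, n_participants=6, n_trials=2)
    proc, excl = process_dataset(generate_dataset(params))
    assert not excl
    return proc


@pytest.fixture(scope="session")
def one_profile(default_params):
    return make_cohort(3, default_params)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
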