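import numpy as np
import pytest

from pcdr import GenerativeTruth, GroupPriors, reml_fit, simulate_profiles


@pytest.fixture(scope="session")
def default_truth():
    return GenerativeTruth(seed=20260101)


@pytest.fixture(scope="session")
def overlap_truth():
    return GenerativeTruth.overlapping(seed=20260102)


@pytest.fixture(scope="session")
def training_profiles(default_truth):
    """A medium training set drawn from the default truth."""
    profiles, _ = simulate_profiles(default_truth, 150, 100)
    return profiles


@pytest.fixture(scope="session")
def fitted_model(training_profiles):
    return reml_fit(training_profiles, order=2)


@pytest.fixture(scope="session")
def overlap_model(overlap_truth):
    profiles, _ = simulate_profiles(overlap_truth, 200, 200)
    return reml_fit(profiles, order=2)


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)


@pytest.fixture(scope="session")
def equal_priors():
    return GroupPriors(0.5, 0.5)
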