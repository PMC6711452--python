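import numpy as np
import pytest

import agedelta as ad


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick Sim1-style cohort for pipeline-level tests."""
    return ad.simulate_cohort(n_subjects=400, n_features=120,
                              n_components=20, seed=42)


def make_instance(n, d, seed):
    """Small random (X demeaned, Y demeaned) instance for oracle tests."""
    r = np.random.default_rng(seed)
    ages = r.uniform(45, 75, n)
    X = r.standard_normal((n, d))
    Y = ad.AgeVector.from_raw(ages)
    return ad.FeatureMatrix.from_raw(X), Y
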