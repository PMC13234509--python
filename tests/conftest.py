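import numpy as np
import pytest

from spikesplit import RatioLibrary, em_fit


@pytest.fixture(scope="session")
def library():
    return RatioLibrary()


@pytest.fixture(scope="session")
def two_cluster_data():
    """2000 draws: 75% N(10,1), 25% N(20,1), with known labels."""
    rng = np.random.default_rng(42)
    low = rng.normal(10.0, 1.0, 1500)
    high = rng.normal(20.0, 1.0, 500)
    values = np.concatenate([low, high])
    labels = np.concatenate([np.zeros(1500, int), np.ones(500, int)])
    return values, labels


@pytest.fixture(scope="session")
def two_cluster_fit(two_cluster_data):
    values, _ = two_cluster_data
    return em_fit(values, seed=7)


def assert_ll_monotone(fit):
    """EM log-likelihood must never decrease across iterations."""
    diffs = np.diff(fit.log_likelihood_trace)
    assert np.all(diffs >= -1e-7 * np.maximum(np.abs(fit.log_likelihood_trace[:-1]), 1.0)), (
        "log-likelihood decreased during EM"
    )
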