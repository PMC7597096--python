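import numpy as np
import pytest

from lqreg import Dataset, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(n=50, d=5, seed=0, slopes=None, intercept=0.0, q_noise=None, noise_scale=1.0):
    """Random standardized dataset with a linear signal and Gaussian (or t) noise."""
    rng = np.random.default_rng(seed)
    X_raw = rng.standard_normal((n, d))
    if slopes is None:
        slopes = np.zeros(d)
    data0, _ = standardize(X_raw, np.zeros(n))
    design = data0.X[:, 1:]
    if q_noise is None or q_noise == 1.0:
        eps = rng.standard_normal(n)
    else:
        nu = (3.0 - q_noise) / (q_noise - 1.0)
        eps = rng.standard_t(nu, size=n)
    y = intercept + design @ np.asarray(slopes, dtype=float) + noise_scale * eps
    return Dataset(np.column_stack([np.ones(n), design]), y)


@pytest.fixture
def dataset_factory():
    return make_dataset
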