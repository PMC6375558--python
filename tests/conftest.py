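"""Shared fixtures: small survival datasets and imputed designs."""

import numpy as np
import pytest

from chrde.data import SurvivalDataset, impute_censored
from chrde.synthetic import SyntheticDesign, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """60 samples, 8 features, moderate censoring, known sparse signal."""
    n, k = 60, 8
    X = rng.standard_normal((n, k))
    beta = np.zeros(k)
    beta[:3] = [1.5, -1.0, 0.8]
    y = 0.3 + X @ beta + 0.3 * rng.standard_normal(n)
    c = np.quantile(y, 0.75) + 0.2 * rng.standard_normal(n)
    delta = (y <= c).astype(float)
    tau = np.exp(np.minimum(y, c))
    return SurvivalDataset(X, tau, delta)


@pytest.fixture
def small_imputed(small_dataset):
    return impute_censored(small_dataset)


@pytest.fixture
def toy_design():
    """Scaled-down grouped design: 10 groups (110 features), 120 samples."""
    return SyntheticDesign(n_kf=10, n_samples=120, rho=0.5, seed=7)


@pytest.fixture
def toy_data(toy_design):
    return generate(toy_design)
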