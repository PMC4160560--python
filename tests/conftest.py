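import warnings

import numpy as np
import pytest

from metatau import (
    MetaRegressionDataset,
    ScenarioSpec,
    SmallSampleWarning,
    simulate_dataset,
)


def random_dataset(seed, n=8, p=2, tau2=0.1, sigma2_range=(0.05, 0.5)):
    """Random meta-regression instance with a continuous covariate.

    Deliberately small instances; the few-studies advisory warning is
    silenced here.
    """
    rng = np.random.default_rng(seed)
    cov = rng.uniform(-1.0, 1.0, size=(n, p - 1)) if p > 1 else None
    sigma2 = np.exp(rng.uniform(np.log(sigma2_range[0]), np.log(sigma2_range[1]), n))
    X = np.column_stack([np.ones(n)] + ([cov] if cov is not None else []))
    beta = rng.normal(0.0, 1.0, size=p)
    y = X @ beta + np.sqrt(sigma2 + tau2) * rng.standard_normal(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallSampleWarning)
        return MetaRegressionDataset(y=y, X=X, sigma2=sigma2)


@pytest.fixture
def example16():
    """Heterogeneous 16-study dataset, intercept + binary covariate (p=2),
    the shape of a dose-group meta-regression; Q(0) well above n - p = 14."""
    spec = ScenarioSpec(n=16, design="intercept+binary", beta=(0.5, 0.9),
                        tau2=0.2, sigma2_law=("log-uniform", 0.02, 0.5), seed=7)
    return simulate_dataset(spec, 0)


@pytest.fixture
def homogeneous_ds():
    """Effects almost exactly on the regression plane with large sigma_i^2:
    the observed statistics sit far below their null quantiles."""
    rng = np.random.default_rng(42)
    n = 12
    x = rng.uniform(-1, 1, n)
    X = np.column_stack([np.ones(n), x])
    beta = np.array([0.4, 0.6])
    y = X @ beta + 1e-4 * rng.standard_normal(n)
    return MetaRegressionDataset(y=y, X=X, sigma2=np.full(n, 1.0))
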