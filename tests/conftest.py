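import numpy as np
import pytest

from zicount import CountModel


@pytest.fixture
def rng():
    return np.random.default_rng(20230927)


def simulate_nb_regression(rng, n, beta, r, treat_prob=0.5):
    """Small NB-regression dataset with intercept + one binary covariate."""
    X = np.column_stack([np.ones(n), (rng.random(n) < treat_prob).astype(float)])
    m = np.exp(X @ np.asarray(beta))
    y = rng.poisson(rng.gamma(r, m / r))
    return y, X


def simulate_zinb_regression(rng, n, beta, gamma, r):
    X = np.column_stack([np.ones(n), (rng.random(n) < 0.5).astype(float)])
    m = np.exp(X @ np.asarray(beta))
    y = rng.poisson(rng.gamma(r, m / r))
    p = 1.0 / (1.0 + np.exp(-(X @ np.asarray(gamma))))
    y = np.where(rng.random(n) < p, 0, y)
    return y, X


@pytest.fixture
def nb_dataset(rng):
    y, X = simulate_nb_regression(rng, 600, beta=[0.2, -0.5], r=0.6)
    return y, X


@pytest.fixture
def zinb_fit(rng):
    y, X = simulate_zinb_regression(rng, 800, beta=[0.5, -0.4], gamma=[-1.2, 0.3], r=0.8)
    model = CountModel(y, X, exog_infl=X, family="zinb")
    return model.fit()
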