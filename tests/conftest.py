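import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_covariates():
    """Covariates with no relation to anything; student-cohort ranges."""

    def _make(n, seed=0):
        r = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "age": r.uniform(18, 28, n),
                "sex": r.integers(0, 2, n).astype(float),
                "mean_fd": r.lognormal(np.log(0.1), 0.4, n),
            }
        )

    return _make


def single_mode_blocks(seed, n=300, p=200, q=17, rho=0.85, sigma=1.0):
    """One planted latent mode with random unit-norm loadings.

    Noise calibration: with X = s z a' + sigma E the population canonical
    correlation is s^2/(s^2+sigma^2), so s = sigma*sqrt(rho/(1-rho)).
    """
    r = np.random.default_rng(seed)
    a = r.standard_normal(p)
    a /= np.linalg.norm(a)
    b = r.standard_normal(q)
    b /= np.linalg.norm(b)
    s = sigma * np.sqrt(rho / (1 - rho))
    z = r.standard_normal(n)
    X = s * np.outer(z, a) + sigma * r.standard_normal((n, p))
    Y = s * np.outer(z, b) + sigma * r.standard_normal((n, q))
    return X, Y, a, b, z


def zscore(M):
    M = np.asarray(M, dtype=float)
    return (M - M.mean(0)) / M.std(0, ddof=1)
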