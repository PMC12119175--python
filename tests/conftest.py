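import numpy as np
import pandas as pd
import pytest

from habseg import simulate


@pytest.fixture(scope="session")
def replica():
    """One deterministic study-replica dataset (81 transects)."""
    return simulate.generate_study_replica(11)


@pytest.fixture(scope="session")
def small_sim():
    """A small generic simulated dataset for cheap fitting tests."""
    cfg = simulate.SimulationConfig(seed=5, n_transects=120, n_sites=40,
                                    sigma_year=0.3)
    return simulate.generate_dataset(cfg)


def make_glm_frame(rng, n=300, beta=(0.5, -0.5), intercept=-3.0,
                   effort=100, n_years=5, sigma_year=0.0, species="count_af",
                   theta=None):
    """Simple simulated frame with z-scored covariates x1, x2, ..."""
    p = len(beta)
    X = rng.normal(size=(n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    years = 2000 + rng.integers(0, n_years, size=n)
    u = dict(zip(range(2000, 2000 + n_years),
                 rng.normal(0, sigma_year, size=n_years)))
    eta = intercept + X @ np.array(beta) + np.array([u[y] for y in years])
    mu = effort * np.exp(eta)
    if theta is None:
        y = rng.poisson(mu)
    else:
        y = rng.poisson(rng.gamma(theta, mu / theta))
    df = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(p)])
    df[species] = y
    df["effort"] = effort
    df["year"] = years
    return df
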