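import numpy as np
import pytest

from platsem import (
    ModelSpec,
    faecalibacterium_correlations,
    fit_model,
)


@pytest.fixture(scope="session")
def table1():
    """Four-platform correlation matrix (N=142) shipped with the package."""
    return faecalibacterium_correlations()


@pytest.fixture(scope="session")
def four_modality_fit(table1):
    """Free one-factor fit to the four-platform correlation matrix."""
    return fit_model(table1, ModelSpec(indicator_names=list(table1.names)))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def random_one_factor_moments(rng, m=3, n_strength=1.0):
    """A random positive-definite moment matrix generated from a one-factor
    truth plus a small symmetric perturbation (stays PD)."""
    lam = np.concatenate([[1.0], rng.uniform(0.4, 1.6, m - 1)])
    szeta = rng.uniform(0.5, 2.0)
    serr = rng.uniform(0.2, 1.0, m)
    S = szeta * np.outer(lam, lam) + np.diag(serr)
    E = rng.normal(0, 0.02 * n_strength, (m, m))
    S = S + E @ E.T
    return S
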