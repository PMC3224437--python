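"""Shared fixtures: simulated ensembles and synthetic Gaussian data."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ggmetab.kinetics import ConcentrationEnsemble, simulate_ensemble
from ggmetab.networks import make_network


def mvn_from_precision(omega: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Sample n rows from N(0, omega^{-1})."""
    rng = np.random.default_rng(seed)
    cov = np.linalg.inv(omega)
    L = np.linalg.cholesky(cov)
    return rng.standard_normal((n, omega.shape[0])) @ L.T


def chain_precision(m: int, strength: float = 0.3) -> np.ndarray:
    """Tridiagonal precision with adjacent partial correlations = strength."""
    omega = np.eye(m)
    for i in range(m - 1):
        omega[i, i + 1] = omega[i + 1, i] = -strength
    return omega


@pytest.fixture(scope="session")
def chain_reversible_ensemble() -> ConcentrationEnsemble:
    return simulate_ensemble(make_network("chain_reversible"), sigma=0.2, n_samples=1000, seed=11)


@pytest.fixture(scope="session")
def gaussian_chain_data() -> pd.DataFrame:
    """n=2000 draws from a 5-variable chain-structured Gaussian."""
    X = mvn_from_precision(chain_precision(5, 0.4), 2000, seed=7)
    return pd.DataFrame(X, columns=list("ABCDE"))
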