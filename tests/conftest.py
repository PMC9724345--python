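"""Shared fixtures: small synthetic landscapes, surveys and fitted models.

Everything is generated programmatically with fixed seeds; the sizes are
kept small so the full suite runs quickly on one CPU.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit

from ancmbg.geostat import MaternParams, ModelSpec, fit, matern_correlation
from ancmbg.survey import SurveyDataset
from ancmbg.synthetic import LandscapeConfig, TruthParams, generate_landscape


def simulate_cluster_dataset(seed: int, m: int = 120, n_per: int = 25,
                             beta=(0.85, 0.5), sigma2: float = 1.0,
                             phi: float = 15.0, nu: float = 1.0,
                             tau2: float = 0.1, extent: float = 150.0,
                             covariate: bool = True) -> SurveyDataset:
    """Cluster survey straight from the generative model on random sites."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, extent, size=(m, 2))
    beta = np.asarray(beta, dtype=float)
    x1 = rng.normal(0, 1, m) if covariate else np.zeros(m)
    eta = beta[0] + (beta[1] * x1 if len(beta) > 1 else 0.0)
    if sigma2 > 0:
        D = squareform(pdist(coords))
        R = matern_correlation(D, phi, nu)
        L = np.linalg.cholesky(sigma2 * R + 1e-8 * np.eye(m))
        eta = eta + L @ rng.standard_normal(m)
    if tau2 > 0:
        eta = eta + rng.normal(0, np.sqrt(tau2), m)
    y = rng.binomial(n_per, expit(eta))
    df = pd.DataFrame({
        "cluster_id": np.arange(m), "x": coords[:, 0], "y": coords[:, 1],
        "n_women": n_per, "n_anc4": y, "ntl": x1,
    })
    return SurveyDataset(df, ["ntl"] if covariate else [])


SMALL_LANDSCAPE = LandscapeConfig(width_km=60.0, height_km=60.0,
                                  resolution_km=3.0, district_grid=(2, 2),
                                  n_centres=2, n_facilities=8,
                                  total_pregnancies=50_000.0)


@pytest.fixture(scope="session")
def small_landscape():
    return generate_landscape(SMALL_LANDSCAPE, seed=42)


@pytest.fixture(scope="session")
def truth_params():
    return TruthParams(beta=np.array([0.85, 0.5]), covariates=["ntl"],
                       matern=MaternParams(1.0, 15.0, 1.0, 0.1))


@pytest.fixture(scope="session")
def sim_dataset():
    return simulate_cluster_dataset(seed=7, m=120)


@pytest.fixture(scope="session")
def fitted_model(sim_dataset):
    result = fit(sim_dataset, ModelSpec(covariates=["ntl"]), seed=0)
    assert result.converged
    return result
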