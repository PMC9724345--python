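"""Core model machinery: Matérn correlation, likelihood, Laplace marginal, fit."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import binom

from ancmbg.geostat import (MaternParams, ModelSpec, binomial_loglik, fit,
                            laplace_log_marginal, latent_mode,
                            matern_correlation)
from ancmbg.survey import SurveyDataset
from conftest import simulate_cluster_dataset


# ------------------------------------------------------ Matérn correlation
def test_matern_at_zero_and_decay():
    assert matern_correlation(0.0, 10.0, 1.0) == 1.0
    assert matern_correlation(100.0 * 10.0, 10.0, 1.0) < 1e-10


def test_matern_exponential_closed_form():
    """nu = 1/2 reduces to exp(-u/phi); at u = phi this is 1/e."""
    assert matern_correlation(10.0, 10.0, 0.5) == pytest.approx(
        np.exp(-1.0), abs=1e-12)
    u = np.linspace(0.0, 80.0, 200)
    np.testing.assert_allclose(matern_correlation(u, 7.0, 0.5),
                               np.exp(-u / 7.0), atol=1e-12)


@pytest.mark.parametrize("nu", [0.5, 1.0, 1.5, 2.5, 50.0])
def test_matern_monotone_nonincreasing(nu):
    u = np.linspace(0.0, 100.0, 500)
    rho = matern_correlation(u, 12.0, nu)
    assert np.all(np.diff(rho) <= 1e-12)
    assert np.all((rho >= 0.0) & (rho <= 1.0))


def test_matern_rejects_bad_parameters():
    with pytest.raises(ValueError):
        matern_correlation(1.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        matern_correlation(1.0, 1.0, -1.0)


# -------------------------------------------------------------- likelihood
def _dataset_from_arrays(coords, y, n, cov=None):
    df = pd.DataFrame({"cluster_id": range(len(y)),
                       "x": coords[:, 0], "y": coords[:, 1],
                       "n_women": n, "n_anc4": y})
    names = []
    if cov is not None:
        df["c1"] = cov
        names = ["c1"]
    return SurveyDataset(df, names)


def test_loglik_fair_coin():
    ds = _dataset_from_arrays(np.zeros((1, 2)), [1], [1])
    assert binomial_loglik(np.zeros(1), np.zeros(1), ds) == pytest.approx(
        np.log(0.5))


def test_loglik_all_failures_limit():
    ds = _dataset_from_arrays(np.zeros((3, 2)), [0, 0, 0], [4, 7, 2])
    val = binomial_loglik(np.full(3, -40.0), np.zeros(1), ds)
    assert val == pytest.approx(0.0, abs=1e-10)   # sum log C(n,0) = 0


def test_loglik_matches_pmf_oracle():
    rng = np.random.default_rng(0)
    m = 12
    coords = rng.uniform(0, 10, (m, 2))
    n = rng.integers(1, 30, m)
    y = rng.integers(0, n + 1)
    cov = rng.normal(0, 1, m)
    latent = rng.normal(0, 1, m)
    beta = np.array([0.4, -0.7])
    ds = _dataset_from_arrays(coords, y, n, cov)
    eta = beta[0] + beta[1] * cov + latent
    expected = binom.logpmf(y, n, expit(eta)).sum()
    assert binomial_loglik(latent, beta, ds) == pytest.approx(expected,
                                                              rel=1e-12)


# ------------------------------------------------------------- latent mode
def test_latent_mode_infinite_shrinkage():
    rng = np.random.default_rng(1)
    coords = rng.uniform(0, 50, (8, 2))
    ds = _dataset_from_arrays(coords, rng.integers(0, 10, 8), np.full(8, 10))
    s, H = latent_mode(MaternParams(1e-12, 10.0, 1.0, 1e-12),
                       np.zeros(1), ds)
    np.testing.assert_allclose(s, 0.0, atol=1e-6)


def test_latent_mode_flat_prior_matches_glm():
    """One cluster, huge prior variance: mode -> logit(y/n) - intercept."""
    ds = _dataset_from_arrays(np.zeros((1, 2)), [70], [100])
    intercept = 0.3
    s, H = latent_mode(MaternParams(1e4, 10.0, 1.0, 0.0),
                       np.array([intercept]), ds)
    assert s[0] == pytest.approx(np.log(0.7 / 0.3) - intercept, abs=1e-3)


def test_latent_mode_gradient_certificate():
    rng = np.random.default_rng(2)
    m = 20
    coords = rng.uniform(0, 80, (m, 2))
    n = np.full(m, 15)
    y = rng.integers(0, 16, m)
    ds = _dataset_from_arrays(coords, y, n)
    theta = MaternParams(0.8, 20.0, 1.0, 0.2)
    s, H = latent_mode(theta, np.array([0.1]), ds)
    # gradient of the penalised loglik at the mode must vanish
    from scipy.spatial.distance import pdist, squareform
    from scipy import linalg
    from ancmbg.geostat import matern_covariance
    Sigma = matern_covariance(squareform(pdist(ds.coords)), theta)
    p = expit(0.1 + s)
    g = (ds.y - ds.n * p) - linalg.solve(Sigma, s, assume_a="pos")
    assert np.max(np.abs(g)) < 1e-6


# --------------------------------------------------------- Laplace marginal
def test_marginal_tiny_variance_equals_glm():
    """sigma2 = tau2 ~ 0: the marginal collapses to the plain binomial GLM."""
    ds = simulate_cluster_dataset(seed=3, m=40, sigma2=0.0, tau2=0.0)
    theta = MaternParams(1e-12, 10.0, 1.0, 1e-12)
    value, beta_hat = laplace_log_marginal(theta, ds, ["ntl"])
    X = ds.design_matrix(["ntl"])
    glm = sm.GLM(np.column_stack([ds.y, ds.n - ds.y]), X,
                 family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(beta_hat, glm.params, atol=1e-5)
    assert value == pytest.approx(glm.llf, abs=1e-6)


def test_marginal_invariant_to_cluster_order():
    ds = simulate_cluster_dataset(seed=4, m=30)
    theta = MaternParams(0.8, 15.0, 1.0, 0.1)
    v1, b1 = laplace_log_marginal(theta, ds, ["ntl"])
    perm = np.random.default_rng(0).permutation(30)
    ds2 = SurveyDataset(ds.df.iloc[perm].reset_index(drop=True), ["ntl"])
    v2, b2 = laplace_log_marginal(theta, ds2, ["ntl"])
    assert v1 == pytest.approx(v2, abs=1e-7)
    np.testing.assert_allclose(b1, b2, atol=1e-7)


def test_marginal_invariant_to_translation():
    """Covariance depends on distances only."""
    ds = simulate_cluster_dataset(seed=5, m=25)
    theta = MaternParams(0.8, 15.0, 1.0, 0.1)
    v1, _ = laplace_log_marginal(theta, ds, ["ntl"])
    df = ds.df.copy()
    df["x"] += 1234.5
    df["y"] -= 987.0
    v2, _ = laplace_log_marginal(theta, SurveyDataset(df, ["ntl"]), ["ntl"])
    assert v1 == pytest.approx(v2, rel=1e-9)


def test_corrected_laplace_close_to_quadrature_path():
    """The production Laplace path agrees with exact quadrature at its
    known accuracy (~1% on these tiny, strongly non-Gaussian problems)."""
    rng = np.random.default_rng(6)
    coords = rng.uniform(0, 50, (4, 2))
    for k in range(5):
        y = rng.integers(0, 3, 4)
        ds = _dataset_from_arrays(coords, y, np.full(4, 2))
        theta = MaternParams(float(rng.uniform(0.1, 1.5)), 15.0, 1.0,
                             float(rng.uniform(0.01, 0.5)))
        beta0 = np.array([float(rng.normal(0, 0.8))])
        v_quad, _ = laplace_log_marginal(theta, ds, [], beta=beta0,
                                         method="aghq")
        v_lap, _ = laplace_log_marginal(theta, ds, [], beta=beta0,
                                        method="laplace")
        assert v_lap == pytest.approx(v_quad, rel=2e-2)


# ---------------------------------------------------------------------- fit
def test_fit_requires_enough_clusters():
    ds = simulate_cluster_dataset(seed=7, m=5)
    with pytest.raises(ValueError):
        fit(ds, ModelSpec(covariates=["ntl"]))


def test_fit_deterministic_given_seed():
    ds = simulate_cluster_dataset(seed=8, m=40)
    spec = ModelSpec(covariates=["ntl"], n_starts=2)
    a = fit(ds, spec, seed=3)
    b = fit(ds, spec, seed=3)
    np.testing.assert_array_equal(a.beta_hat, b.beta_hat)
    assert a.theta_hat == b.theta_hat
    assert a.log_marginal == b.log_marginal
    np.testing.assert_array_equal(a.latent_mode, b.latent_mode)


def test_fit_null_field_estimates_small_sigma2():
    """Data with no spatial field: sigma2_hat should be near zero."""
    sig = []
    for r in range(8):
        ds = simulate_cluster_dataset(seed=300 + r, m=50, sigma2=0.0,
                                      tau2=0.0)
        fr = fit(ds, ModelSpec(covariates=["ntl"], n_starts=3), seed=r)
        sig.append(fr.theta_hat.sigma2)
    assert np.median(sig) < 0.05


def test_fit_roundtrip_json(tmp_path, fitted_model):
    path = tmp_path / "fit.json"
    fitted_model.to_json(path)
    from ancmbg.geostat import FitResult
    back = FitResult.from_json(path)
    np.testing.assert_allclose(back.beta_hat, fitted_model.beta_hat)
    assert back.theta_hat == fitted_model.theta_hat
    assert back.converged == fitted_model.converged
    np.testing.assert_allclose(back.latent_precision,
                               fitted_model.latent_precision)


def test_fit_recovers_truth_roughly(fitted_model):
    """Single-replicate sanity: estimates in the right ballpark (the full
    coverage calibration lives in the acceptance suite)."""
    th = fitted_model.theta_hat
    assert 0.2 < th.sigma2 < 5.0
    assert 3.0 < th.phi < 80.0
    se0 = np.sqrt(fitted_model.beta_vcov[0, 0])
    assert abs(fitted_model.beta_hat[0] - 0.85) < 4 * se0
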