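"""Descriptive estimates, covariate selection and variogram machinery."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ancmbg.exploratory import (covariate_correlation, empirical_logit,
                                empirical_variogram, residual_correlation_test,
                                select_covariates, weighted_proportion)
from ancmbg.survey import SurveyDataset
from conftest import simulate_cluster_dataset


# ------------------------------------------------------ weighted proportion
def test_weighted_proportion_hand_arithmetic():
    """(8/10, w=1) and (2/10, w=3): (8 + 6) / (10 + 30) = 35%."""
    est = weighted_proportion([8, 2], [10, 10], [1.0, 3.0])
    assert est.percent == pytest.approx(35.0)


def test_weighted_proportion_symmetric_ci_at_half():
    est = weighted_proportion([5, 5], [10, 10], [1.0, 1.0])
    assert est.percent == pytest.approx(50.0)
    # symmetry on the logit scale maps to symmetry around 50%
    assert est.percent - est.lower == pytest.approx(est.upper - est.percent)


def test_weighted_proportion_boundary_degenerate():
    est = weighted_proportion([10], [10], [1.0])
    assert est.percent == 100.0
    assert est.upper == 100.0
    assert est.lower < 100.0


def test_unit_weights_equal_pooled():
    rng = np.random.default_rng(0)
    n = rng.integers(5, 40, 30)
    y = rng.binomial(n, 0.6)
    est = weighted_proportion(y, n)
    assert est.percent == pytest.approx(100.0 * y.sum() / n.sum(), abs=1e-12)
    assert est.n_effective == pytest.approx(n.sum())


def test_weighted_proportion_errors():
    with pytest.raises(ValueError):
        weighted_proportion([1], [2], [0.0])
    with pytest.raises(ValueError):
        weighted_proportion([3], [2], [1.0])


# ------------------------------------------------------------ empirical logit
def test_empirical_logit_values():
    assert empirical_logit(5, 10) == pytest.approx(0.0)
    assert empirical_logit(0, 10) == pytest.approx(np.log(0.5 / 10.5))
    assert empirical_logit(10, 10) == pytest.approx(-empirical_logit(0, 10))


def test_empirical_logit_antisymmetry_vectorised():
    y = np.arange(0, 21)
    np.testing.assert_allclose(empirical_logit(y, 20),
                               -empirical_logit(20 - y, 20), atol=1e-14)


# ----------------------------------------------------------- correlation
def _tiny_dataset(cols: dict) -> SurveyDataset:
    m = len(next(iter(cols.values())))
    df = pd.DataFrame({"cluster_id": range(m), "x": np.arange(m, dtype=float),
                       "y": np.zeros(m), "n_women": 10, "n_anc4": 5, **cols})
    return SurveyDataset(df, list(cols))


def test_correlation_identity_and_antisymmetry():
    x = np.array([1.0, 2, 3, 4, 5])
    ds = _tiny_dataset({"a": x, "b": -x, "c": 2 * x})
    res = covariate_correlation(ds)
    assert res.matrix.loc["a", "a"] == pytest.approx(1.0)
    assert res.matrix.loc["a", "b"] == pytest.approx(-1.0)
    assert res.matrix.loc["a", "c"] == pytest.approx(1.0)
    flagged = {(p[0], p[1]) for p in res.collinear_pairs}
    assert ("a", "b") in flagged and ("a", "c") in flagged


def test_correlation_zero_variance_flagged():
    ds = _tiny_dataset({"a": np.array([1.0, 2, 3, 4, 5]),
                        "z": np.ones(5)})
    res = covariate_correlation(ds)
    assert res.zero_variance == ["z"]
    assert np.isnan(res.matrix.loc["z", "a"])


# ------------------------------------------------------------- selection
def _glm_dataset(rng, m, signal: bool):
    x = rng.normal(0, 1, m)
    eta = 0.3 + (1.0 * x if signal else 0.0)
    n = 25
    y = rng.binomial(n, expit(eta))
    df = pd.DataFrame({"cluster_id": range(m), "x": rng.uniform(0, 100, m),
                       "y": rng.uniform(0, 100, m),
                       "n_women": n, "n_anc4": y, "cand": x})
    return SurveyDataset(df, ["cand"])


def test_selection_excludes_noise_and_keeps_signal():
    rng = np.random.default_rng(1)
    excluded = sum("cand" not in
                   select_covariates(_glm_dataset(rng, 500, False)).selected
                   for _ in range(50))
    assert excluded >= 40        # pure-noise candidate dropped >= 80%
    kept = sum("cand" in
               select_covariates(_glm_dataset(rng, 500, True)).selected
               for _ in range(20))
    assert kept == 20            # strong signal always retained


def test_selection_empty_candidates_is_intercept_only():
    rng = np.random.default_rng(2)
    ds = _glm_dataset(rng, 50, False)
    res = select_covariates(ds, [])
    assert res.selected == []
    assert set(res.coefficients) == {"intercept"}
    assert np.isfinite(res.aic)


def test_selection_criterion_non_increasing():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 200)
    df = pd.DataFrame({"cluster_id": range(200),
                       "x": rng.uniform(0, 100, 200),
                       "y": rng.uniform(0, 100, 200),
                       "n_women": 20,
                       "n_anc4": rng.binomial(20, expit(0.2 + 0.8 * x)),
                       "a": x, "b": rng.normal(0, 1, 200),
                       "c": rng.normal(0, 1, 200)})
    res = select_covariates(SurveyDataset(df, ["a", "b", "c"]))
    aics = [s["aic"] for s in res.steps]
    assert all(a2 <= a1 + 1e-9 for a1, a2 in zip(aics, aics[1:]))
    assert set(res.selected) <= {"a", "b", "c"}
    assert "a" in res.selected


# -------------------------------------------------------------- variogram
def test_variogram_constant_field_is_zero():
    rng = np.random.default_rng(0)
    coords = rng.uniform(0, 10, (20, 2))
    vg = empirical_variogram(np.full(20, 3.7), coords)
    filled = vg.pair_count > 0
    assert np.allclose(vg.semivariance[filled], 0.0)


def test_variogram_single_pair_formula():
    coords = np.array([[0.0, 0.0], [4.0, 0.0]])
    vg = empirical_variogram(np.array([1.0, 3.0]), coords,
                             bin_edges=np.array([0.0, 10.0]))
    assert vg.semivariance[0] == pytest.approx(2.0)   # (3-1)^2 / 2
    assert vg.pair_count[0] == 1


def test_variogram_matches_bruteforce():
    rng = np.random.default_rng(4)
    coords = rng.uniform(0, 50, (50, 2))
    vals = rng.normal(0, 1, 50)
    edges = np.linspace(0, 40, 9)
    vg = empirical_variogram(vals, coords, edges)
    # O(n^2) double loop with half-open bins
    sums = np.zeros(8)
    counts = np.zeros(8, dtype=int)
    for i in range(50):
        for j in range(i + 1, 50):
            d = np.hypot(*(coords[i] - coords[j]))
            for b in range(8):
                if edges[b] <= d < edges[b + 1]:
                    sums[b] += (vals[i] - vals[j]) ** 2
                    counts[b] += 1
    np.testing.assert_array_equal(vg.pair_count, counts)
    expect = np.where(counts > 0, sums / (2 * np.maximum(counts, 1)), np.nan)
    np.testing.assert_allclose(vg.semivariance, expect, rtol=1e-12)


def test_variogram_rejects_bad_input():
    with pytest.raises(ValueError):
        empirical_variogram(np.array([1.0]), np.array([[0.0, 0.0]]))
    with pytest.raises(ValueError):
        empirical_variogram(np.array([1.0, 2.0]),
                            np.array([[0.0, 0.0], [1.0, 1.0]]),
                            bin_edges=np.array([1.0, 0.5]))


# ----------------------------------------------- residual correlation test
def test_residual_test_deterministic():
    ds = simulate_cluster_dataset(seed=10, m=80, sigma2=0.0, tau2=0.0)
    a = residual_correlation_test(ds, ["ntl"], n_permutations=99, seed=5)
    b = residual_correlation_test(ds, ["ntl"], n_permutations=99, seed=5)
    np.testing.assert_array_equal(a.lower, b.lower)
    np.testing.assert_array_equal(a.upper, b.upper)
    assert a.p_value == b.p_value


def test_residual_test_requires_enough_permutations():
    ds = simulate_cluster_dataset(seed=10, m=40, sigma2=0.0)
    with pytest.raises(ValueError):
        residual_correlation_test(ds, ["ntl"], n_permutations=10)


def test_residual_test_calibration_and_power():
    """i.i.d. residuals rarely flagged; a strong Matérn field almost always."""
    null_flags = sum(
        residual_correlation_test(
            simulate_cluster_dataset(seed=100 + r, m=100, sigma2=0.0,
                                     tau2=0.3, extent=100.0),
            ["ntl"], n_permutations=199, seed=r).evidence
        for r in range(50))
    assert null_flags <= 5           # no evidence in >= 90% of replicates
    power_flags = sum(
        residual_correlation_test(
            simulate_cluster_dataset(seed=200 + r, m=100, sigma2=1.0,
                                     phi=30.0, tau2=0.0, extent=100.0),
            ["ntl"], n_permutations=199, seed=r).evidence
        for r in range(50))
    assert power_flags >= 45         # evidence in >= 90% of replicates
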