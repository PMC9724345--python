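"""Posterior simulation of the coverage surface and exceedance probabilities.

Prediction draws propagate two sources of uncertainty under the plug-in
covariance parameters: the Gaussian (Laplace) approximation to the latent
field at the data sites, and the Gaussian approximation to the fixed
effects.  Each draw kriges the spatial component S to the prediction grid
and applies the inverse logit; the nugget is cluster-level noise and is
excluded from the predicted (stable) coverage surface by default.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.special import expit

from .geostat import FitResult, JITTER, matern_correlation, matern_covariance
from .grids import GridSurface
from .survey import SurveyDataset

__all__ = ["PosteriorSamples", "conditional_simulate", "summarize_surface",
           "exceedance_probability"]


@dataclass
class PosteriorSamples:
    """Draws of coverage P(x) at prediction-grid cells.

    samples has shape (n_draws, n_cells_with_data); cell_index maps each
    column to its (row, col) in the template grid.
    """

    template: GridSurface
    cell_index: np.ndarray           # (n_cells, 2) int rows/cols
    locations: np.ndarray            # (n_cells, 2) cell-centre coordinates
    samples: np.ndarray              # (n_draws, n_cells) in (0, 1)
    seed: int
    threshold_default: float = 0.70

    @property
    def n_draws(self) -> int:
        return self.samples.shape[0]

    def to_grid(self, values: np.ndarray) -> GridSurface:
        out = np.full(self.template.values.shape, self.template.nodata)
        out[self.cell_index[:, 0], self.cell_index[:, 1]] = values
        return self.template.copy_with(out)


def conditional_simulate(fit: FitResult, dataset: SurveyDataset,
                         grid: GridSurface,
                         covariate_grids: dict[str, GridSurface] | None = None,
                         n_draws: int = 1000, seed: int = 0,
                         include_nugget: bool = False) -> PosteriorSamples:
    """Simulate the coverage surface on a grid from a fitted model.

    Per draw: beta ~ N(beta_hat, vcov); the latent total (S + Z) at the
    data sites from the Laplace Gaussian approximation N(s_hat, H^{-1});
    S on the grid by conditional Gaussian simulation given that latent
    total under the plug-in Matérn parameters; coverage is
    inverse-logit(d'(x) beta + S(x)).  Cells where any covariate is nodata
    are dropped (never imputed).
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    if n_draws < 1:
        raise ValueError("need at least one draw")
    covariate_grids = covariate_grids or {}
    for name in fit.covariates:
        if name not in covariate_grids:
            raise ValueError(f"no covariate grid supplied for {name!r}")
        if not grid.same_geometry(covariate_grids[name]):
            raise ValueError(f"covariate grid {name!r} not co-registered")

    # prediction cells: centres with full covariate data
    xc, yc = grid.cell_centers()
    ok = grid.mask()
    for name in fit.covariates:
        ok &= covariate_grids[name].mask()
    rows, cols = np.where(ok)
    cell_index = np.column_stack([rows, cols])
    locs = np.column_stack([xc[rows, cols], yc[rows, cols]])
    n_cells = len(locs)
    if n_cells == 0:
        raise ValueError("no prediction cells with complete covariates")

    Xg = np.column_stack(
        [np.ones(n_cells)]
        + [covariate_grids[nm].values[rows, cols] for nm in fit.covariates])

    theta = fit.theta_hat
    data_coords = dataset.coords
    m = len(data_coords)

    # posterior (Laplace) for the latent total u = S + Z at data sites
    H = np.asarray(fit.latent_precision, dtype=float)
    Lh = linalg.cholesky(H, lower=True)
    s_hat = np.asarray(fit.latent_mode, dtype=float)

    # kriging operators under plug-in theta
    D_dd = squareform(pdist(data_coords))
    Sigma_dd = matern_covariance(D_dd, theta)          # sigma2 R + tau2 I
    D_gd = cdist(locs, data_coords)
    C_gd = theta.sigma2 * matern_correlation(D_gd, theta.phi, theta.nu)
    A = linalg.solve(Sigma_dd, C_gd.T, assume_a="pos").T    # (n_cells, m)

    rng = np.random.default_rng(seed)
    if theta.sigma2 > 0:
        D_gg = squareform(pdist(locs))
        C_gg = theta.sigma2 * matern_correlation(D_gg, theta.phi, theta.nu)
        cond_cov = C_gg - A @ C_gd.T
        cond_cov[np.diag_indices(n_cells)] += JITTER * max(theta.sigma2, 1.0)
        L_cond = linalg.cholesky(cond_cov, lower=True)
    else:
        L_cond = None

    vcov = np.asarray(fit.beta_vcov, dtype=float)
    L_beta = linalg.cholesky(vcov + 1e-12 * np.eye(len(vcov)), lower=True)
    beta_hat = np.asarray(fit.beta_hat, dtype=float)

    if include_nugget and theta.tau2 > 0:
        nugget_sd = np.sqrt(theta.tau2)
    else:
        nugget_sd = 0.0

    samples = np.empty((n_draws, n_cells))
    for k in range(n_draws):
        beta = beta_hat + L_beta @ rng.standard_normal(len(beta_hat))
        # latent total at data: N(s_hat, H^{-1}) via H = Lh Lh'
        u = s_hat + linalg.solve_triangular(Lh.T, rng.standard_normal(m),
                                            lower=False)
        S_grid = A @ u
        if L_cond is not None:
            S_grid = S_grid + L_cond @ rng.standard_normal(n_cells)
        eta = Xg @ beta + S_grid
        if nugget_sd > 0:
            eta = eta + rng.normal(0.0, nugget_sd, n_cells)
        samples[k] = expit(eta)

    np.clip(samples, 1e-12, 1.0 - 1e-12, out=samples)
    return PosteriorSamples(template=grid.full_like(0.0),
                            cell_index=cell_index, locations=locs,
                            samples=samples, seed=seed)


def summarize_surface(samples: PosteriorSamples):
    """Mean, standard error and 2.5/97.5 percentile surfaces of the draws."""
    if samples.n_draws < 2:
        raise ValueError("need at least two draws to summarise")
    s = samples.samples
    mean = s.mean(axis=0)
    se = s.std(axis=0, ddof=1)
    lo, hi = np.percentile(s, [2.5, 97.5], axis=0)
    return (samples.to_grid(mean), samples.to_grid(se),
            samples.to_grid(lo), samples.to_grid(hi))


def exceedance_probability(samples: PosteriorSamples,
                           threshold: float | None = None) -> GridSurface:
    """Per-cell fraction of draws with coverage above the target threshold."""
    t = samples.threshold_default if threshold is None else float(threshold)
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    ep = (samples.samples > t).mean(axis=0)
    return samples.to_grid(ep)
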