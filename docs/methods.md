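# Methods

This note documents the statistical model, the estimation machinery, the
synthetic study design, and the numerical and design choices behind
`ancmbg`, at the level of detail a user would need to judge what results
do and do not show.

## Model

Cluster outcomes are binomial with a logit-linear latent structure:

    y_i | P(x_i) ~ Binomial(n_i, P(x_i)),
    logit P(x_i) = d'(x_i) β + S(x_i) + Z_i.

`S` is a stationary, isotropic, zero-mean Gaussian process with Matérn
correlation ρ(u) = 2^{1−ν}/Γ(ν) (u/φ)^ν K_ν(u/φ) and variance σ²
(logit² units); `Z_i ~ N(0, τ²)` is independent per cluster (the
nugget: measurement error and micro-scale variation the field cannot
resolve).  Assumptions worth stating plainly: stationarity and isotropy
of the residual field, correctness of the logit-linear covariate
specification, conditional independence of women within a cluster given
`P(x_i)`, and fixed, known cluster locations — displaced coordinates
are used as-is, mitigated only by buffered covariate extraction.

### Parameters

| parameter | meaning | units | default / bounds |
|---|---|---|---|
| β | fixed effects | logit | profiled, unbounded |
| σ² | field (partial-sill) variance | logit² | optimised in [1e−6, 25] |
| φ | Matérn range | km | optimised in [0.02·diam, 2·diam] of the data extent |
| ν | Matérn smoothness | — | fixed, default 1; {0.5, 1, 1.5, 2.5} sensible |
| τ² | nugget variance | logit² | optimised in [1e−6, 25] |
| threshold | coverage target for EP | proportion | 0.70 (the EPMM district target) |

ν is not identifiable from typical survey designs, so it is fixed, not
estimated; ν = 1 corresponds to the smoothness the common SPDE
formulation (α = 2 in two dimensions) imposes, making results
comparable with mainstream prevalence-mapping practice.

## Estimation

Inference is empirical-Bayes maximum likelihood rather than fully
Bayesian MCMC/INLA: for fixed θ = (σ², φ, τ²) the latent vector is
integrated out approximately, β is profiled by joint Newton
optimisation over (β, s), and θ is maximised in log scale by L-BFGS-B
from five seeded multistart initialisations (one variance-splitting
heuristic from empirical-logit residuals, the rest log-uniform in the
bounds).  Ties between multistart optima are broken by the higher
objective, then the smaller φ.  β's covariance is the Schur complement
of the joint (β, s) curvature at the mode — i.e. latent uncertainty is
propagated into β, while θ̂ is plugged in.  Consequences: intervals do
not carry θ-uncertainty, and "95% CI" surfaces are sampling-based
percentile intervals under the plug-in fit, slightly narrower than a
full posterior would give.

### The marginal likelihood

The integral ∫ L(β, s) N(s; 0, Σ(θ)) ds has no closed form.  The
package evaluates it two ways:

* **≤ 4 clusters:** essentially exactly, by mode-centred tensor
  Gauss–Hermite quadrature (order 25 per dimension).  At these sizes
  quadrature is cheap and removes all approximation error; this mirrors
  how mixed-model software switches to adaptive quadrature when the
  random-effect dimension is small.
* **> 4 clusters (the production path):** a Laplace approximation at
  the penalised-likelihood mode (damped Newton, gradient tolerance
  1e−8, 100-iteration cap) **plus a fourth-order moment correction**.
  Because the non-quadratic part of the integrand separates across
  clusters, the third/fourth derivative tensors are diagonal and the
  correction reduces to O(m²) contractions with the inverse curvature.
  Measured against quadrature on 3-cluster, n = 2 problems over
  σ² ∈ [0.05, 2], τ² ∈ [0.01, 1], the plain Laplace value is off by
  3e−4–2.4e−2 (relative, log scale); the corrected value by 1e−5–3e−3.
  With realistic cluster sizes (n_i ≈ 25) the correction is small but
  costless, and it measurably improves the likelihood surface near
  degenerate fits.

Covariances get a 1e−8·max(σ², 1) diagonal jitter before every
Cholesky factorisation; a non-positive-definite covariance after
jitter raises an error naming ill-conditioned Matérn parameters.
Degenerate data (y ∈ {0, n} everywhere) still fit: initialisation uses
the half-offset empirical logit.

## Prediction

Per posterior draw: β ~ N(β̂, V̂), the latent total u = S + Z at the
data sites from the Laplace Gaussian N(ŝ, H⁻¹), then S on the grid by
the conditional Gaussian given u under plug-in θ̂ (simple kriging of
the field from the noisy total; the cross-covariance excludes the
nugget).  The nugget is *excluded* from the predicted surface by
default — the mapped quantity is the stable coverage surface
d'β + S(x), not a hypothetical new cluster's outcome — and can be
switched on (`include_nugget=True`) when a predictive surface for new
clusters is wanted.  Default 1,000 draws; the conditional covariance is
factorised once and reused across draws, so grids to ~2,500 cells are
interactive.

Exceedance probability is the fraction of draws above the threshold,
computed per pixel and — on the draw-wise population-weighted district
aggregate — per district.  District coverage is pregnancy-weighted
(not a plain pixel mean) so that headcounts equal coverage × population
consistently, and women-with plus women-without equals the district
pregnancy total exactly by construction.  Cells are assigned to
districts by the cell-centre rule; a centre on a shared boundary goes
to the lower district id, deterministically.

## Exploratory stage and validation

* Weighted descriptive estimates use p̂ = Σwy/Σwn with a logit-scale
  Wald CI and the Kish effective sample size (Σwn)²/Σw²n.  This is not
  the Taylor-linearised design-based variance a survey package would
  produce from strata/PSU identifiers; with clustered designs it is
  mildly optimistic.
* Covariate selection: backward elimination by AIC on the cluster-level
  binomial GLM — deterministic given the data; perfect-separation
  failures drop the offending covariate with a warning.
* Residual spatial correlation: the empirical variogram (Matheron
  estimator; 15 equal-width bins to half the maximum pairwise distance
  by default) of empirical-logit GLM residuals, against permutation
  envelopes.  Pointwise 2.5/97.5% bands are reported for plotting, but
  the *verdict* is an exact global min-rank permutation test over the
  short-range bins (centres in the first third of the binned range):
  with ~5 correlated bins, flagging any pointwise excursion would
  reject an i.i.d. truth ~12% of the time, while the global rank test
  is exact at 5% by permutation symmetry (measured 4% over 50 null
  replicates, with 98% power against a strong field).
* Model validation simulates replicate outcome vectors from the fitted
  model at the original locations and bands the residual variogram with
  per-bin 2.5/97.5 percentiles (default 1,000 simulations).  The strict
  "lies entirely inside the band" verdict is reported as `compatible`,
  but with ~15 pointwise bins it rejects a true model ~26% of the time
  (measured over 50 meta-replicates), so the report carries the count
  of outside bins and `compatible_within(k)` for a small-k relaxation;
  two tolerated bins gives 94% self-acceptance while still rejecting a
  10×-inflated range 100% of the time.

## Travel time and the access stratifier

Travel time to the nearest facility is a multi-source Dijkstra on the
8-connected raster graph; edge cost is the mean of the two endpoint
cells' minutes-per-km times the step length (resolution; ×√2 on
diagonals).  Road cells override friction with 60/speed minutes per km;
barrier cells are impassable unless a road crosses them.  The mean-of-
endpoints edge rule is one of several defensible conventions (max and
destination-cell are alternatives); it is symmetric and grid-consistent.
Slope-dependent walking speeds and multi-modal mixing are out of scope —
the friction raster is expected to already encode the effective mode.
Cells at exactly 60 minutes count as good access (the ≤ 1 hour coding);
unreachable cells are marginalized.  Covariates at displaced cluster
coordinates are extracted as buffered means (radius matching the
displacement magnitude, at least one cell size), falling back to the
nearest data cell when a buffer holds only nodata.

## The synthetic study

The generator produces what the analysis needs and nothing more: a
150 × 150 km area at 3 km resolution (the analysis resolution used for
real surveys), 16 rectangular districts, three urban centres, a
nighttime-lights proxy decaying exponentially (25 km scale) from the
centres, a pregnancy raster (500,000 total, largest-remainder rounding
so the total is exact) concentrated near the centres, friction at
3 min/km baseline (mixed walking/vehicle) reduced near urban areas,
60 km/h roads joining the centres, a river barrier with at least one
crossing, and 25 facilities placed preferentially where people are.
Surveys place 150 clusters of 25 women proportional to pregnancy
density, draw outcomes from the model with β = (0.85, 0.5) on the
lights proxy, σ² = 1, φ = 15 km, ν = 1, τ² = 0.1 (giving ~60–70%
coverage with strong spatial structure, the regime of the motivating
surveys), displace coordinates by the confidentiality rules (uniform
distance and bearing, rejection-resampled into the district with a
1,000-retry cap; the 1% long-displacement rural subset is Bernoulli-
selected), and derive strata from the recorded covariates: wealth =
lights proxy below its 40th percentile (the two poorer quintiles),
access = travel time ≤/> 60 minutes (~75/25 with the defaults, close
to the motivating surveys' 79–93% within one hour), education =
Bernoulli with a lights-gradient probability (~75% "some").

What the generator does *not* emulate: two-stage sampling weights with
strata/PSU design effects (weights are mild i.i.d. log-normal),
non-stationarity, covariate measurement error beyond displacement, and
real geography.  Passing tests therefore demonstrate the estimator's
correctness and calibration *under the model's own assumptions*, not
robustness to their violation.

## Numerical and reproducibility notes

* Every stochastic function takes a seed (or `numpy` Generator); the
  pipeline derives stage seeds from the run seed, and the manifest
  records SHA-256 checksums of every output — two runs with the same
  config are byte-identical.
* Variogram bins are half-open [lo, hi); empty bins keep count 0 and
  NaN semivariance rather than being dropped.
* Quantiles use the linear-interpolation rule throughout.
* Simulation sizes in the test suite (e.g. 30 fit replicates of 300
  clusters; 50 envelope meta-replicates at 199 simulations; 199–499
  permutations) are chosen so the whole suite completes in minutes on
  one CPU while keeping Monte-Carlo error well inside the asserted
  margins.
* Rasters are plain-text ESRI ASCII grids and districts GeoJSON, so
  every artifact is diffable and GIS-readable.

## Known limitations

θ-uncertainty is not propagated (plug-in empirical Bayes); design-based
variance for descriptive tables is approximated by effective sample
size; the travel-time model is single-mode; the displacement model
constrains to the analysis district (the confidentiality procedure's
actual constraint region for a given survey may be the coarser survey
region); and aggregation assumes the pregnancy raster and prediction
grid are co-registered (an explicit mass-conserving resampler is
provided for when they are not).
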