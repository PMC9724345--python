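"""Synthetic landscapes and surveys with the generative structure the model assumes.

This module builds a self-contained planar study area — districts, an
urbanization proxy (emulating nighttime lights), a pregnancy-density
raster, a friction surface with roads and a barrier, facilities and a
modelled travel-time covariate — and then simulates cluster surveys from
the binomial geostatistical model itself: a latent Matérn Gaussian field
plus nugget on the logit scale, binomial outcomes, equity-stratum labels
derived from the covariates, and confidentiality displacement of cluster
coordinates (up to 2 km urban / 5 km rural, 1% of rural clusters up to
10 km, always within the district).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit
from shapely.geometry import Point, box

from . import accessibility
from .geostat import MaternParams, matern_correlation
from .grids import GridSurface
from .survey import SurveyDataset

__all__ = [
    "LandscapeConfig", "Landscape", "TruthParams",
    "generate_landscape", "simulate_gaussian_field",
    "simulate_survey", "displace_coordinates",
]

#: displacement radii (km) of the DHS/MIS confidentiality procedure
URBAN_MAX_KM = 2.0
RURAL_MAX_KM = 5.0
RURAL_LONG_MAX_KM = 10.0
RURAL_LONG_PROB = 0.01


@dataclass
class LandscapeConfig:
    """Generation settings for a synthetic study area.

    Defaults give a 150 x 150 km area at the 3-km analysis resolution
    (50 x 50 cells), 16 rectangular districts, three urban centres and a
    facility network of 25 sites.
    """

    width_km: float = 150.0
    height_km: float = 150.0
    resolution_km: float = 3.0
    district_grid: tuple[int, int] = (4, 4)
    n_centres: int = 3
    n_facilities: int = 25
    total_pregnancies: float = 500_000.0
    ntl_decay_km: float = 25.0
    pregnancy_decay_km: float = 35.0
    base_friction_min_per_km: float = 3.0   # mixed walking/vehicle pace
    road_speed_kmh: float = 60.0
    with_barrier: bool = True

    def __post_init__(self) -> None:
        if self.resolution_km <= 0:
            raise ValueError("resolution must be positive")
        if self.district_grid[0] < 1 or self.district_grid[1] < 1:
            raise ValueError("need at least one district")


@dataclass
class Landscape:
    """A synthetic study area: districts, rasters, roads and facilities."""

    bounds: tuple[float, float, float, float]
    resolution_km: float
    districts: list[tuple[int, object]]
    pregnancy_raster: GridSurface
    covariate_rasters: dict[str, GridSurface]
    friction_raster: GridSurface
    facilities: np.ndarray
    roads: dict[tuple[int, int], float] = field(default_factory=dict)
    barriers: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bounds
        area = (x1 - x0) * (y1 - y0)
        from shapely.ops import unary_union
        polys = [p for _, p in self.districts]
        union = unary_union(polys)
        if abs(union.area - area) > 1e-9:
            raise ValueError("districts do not tile the bounds")
        if abs(sum(p.area for p in polys) - area) > 1e-9:
            raise ValueError("districts overlap")
        preg = self.pregnancy_raster
        if (preg.values[preg.mask()] < 0).any():
            raise ValueError("pregnancy counts must be non-negative")
        fric = self.friction_raster
        if (fric.values[fric.mask()] <= 0).any():
            raise ValueError("friction must be positive where not nodata")

    def cost_model(self) -> accessibility.CostModel:
        return accessibility.CostModel(self.friction_raster, dict(self.roads),
                                       set(self.barriers))

    def grid_template(self) -> GridSurface:
        return self.pregnancy_raster.full_like(0.0)


@dataclass
class TruthParams:
    """Ground-truth generative parameters: logit-scale fixed effects plus
    the Matérn field and nugget."""

    beta: np.ndarray
    covariates: list[str]
    matern: MaternParams
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != len(self.covariates) + 1:
            raise ValueError("beta must have one coefficient per covariate "
                             "plus an intercept")


def _line_cells(r0, c0, r1, c1):
    """Cells along a straight segment (dense sampling, unique, ordered)."""
    n = int(max(abs(r1 - r0), abs(c1 - c0)) * 3) + 2
    rr = np.round(np.linspace(r0, r1, n)).astype(int)
    cc = np.round(np.linspace(c0, c1, n)).astype(int)
    seen, out = set(), []
    for rc in zip(rr, cc):
        if rc not in seen:
            seen.add(rc)
            out.append(rc)
    return out


def generate_landscape(config: LandscapeConfig, seed: int = 0) -> Landscape:
    """Build a deterministic-for-seed synthetic study area."""
    res = config.resolution_km
    ncols = int(round(config.width_km / res))
    nrows = int(round(config.height_km / res))
    if ncols < 2 or nrows < 2:
        raise ValueError("landscape too small for the chosen resolution")
    rng = np.random.default_rng(seed)

    template = GridSurface(np.zeros((nrows, ncols)), 0.0, 0.0, res)
    xc, yc = template.cell_centers()

    # urban centres in the interior
    cx = rng.uniform(0.15 * config.width_km, 0.85 * config.width_km,
                     config.n_centres)
    cy = rng.uniform(0.15 * config.height_km, 0.85 * config.height_km,
                     config.n_centres)
    d_centre = np.min(np.sqrt((xc[..., None] - cx) ** 2
                              + (yc[..., None] - cy) ** 2), axis=-1)

    # nighttime-light proxy: deterministic decay with distance to a centre
    ntl = np.exp(-d_centre / config.ntl_decay_km)
    ntl_raster = template.copy_with(ntl)

    # pregnancy raster: mass concentrated near centres, exact configured total
    w = np.exp(-d_centre / config.pregnancy_decay_km) + 0.08
    preg = w / w.sum() * config.total_pregnancies
    preg_int = np.floor(preg)
    shortfall = int(round(config.total_pregnancies - preg_int.sum()))
    if shortfall > 0:  # largest-remainder rounding keeps the total exact
        frac = (preg - preg_int).ravel()
        top = np.argsort(frac)[::-1][:shortfall]
        flat = preg_int.ravel()
        flat[top] += 1
        preg_int = flat.reshape(preg.shape)
    preg_raster = template.copy_with(preg_int)

    # friction: walking, faster near urban areas
    friction = config.base_friction_min_per_km * (1.0 - 0.6 * ntl)
    friction_raster = template.copy_with(friction)

    # roads join consecutive centres; a vertical river barrier with a crossing
    roads: dict[tuple[int, int], float] = {}
    order = np.argsort(cx)
    for a, b in zip(order[:-1], order[1:]):
        r0, c0 = template.index_of(cx[a], cy[a])
        r1, c1 = template.index_of(cx[b], cy[b])
        for rc in _line_cells(int(r0), int(c0), int(r1), int(c1)):
            roads[rc] = config.road_speed_kmh
    barriers: set[tuple[int, int]] = set()
    if config.with_barrier and ncols >= 8:
        bcol = int(0.55 * ncols)
        barriers = {(r, bcol) for r in range(nrows)}
        barriers -= set(roads)  # roads cross the river
        if not any(c == bcol for _, c in roads):
            barriers.discard((nrows // 2, bcol))  # keep a ford: stay connected

    # facilities: placed preferentially where people are
    p = preg_int.ravel() / preg_int.sum()
    cells = rng.choice(nrows * ncols, size=min(config.n_facilities,
                                               nrows * ncols),
                       replace=False, p=p)
    frow, fcol = np.unravel_index(cells, (nrows, ncols))
    fac = np.column_stack([xc[frow, fcol], yc[frow, fcol]])
    # keep facilities off the barrier
    keep = [i for i, rc in enumerate(zip(frow, fcol)) if tuple(rc) not in barriers]
    fac = fac[keep]

    cost = accessibility.CostModel(friction_raster, roads, barriers)
    tt = accessibility.travel_time_map(cost, fac)

    # districts: rectangular partition
    gr, gc = config.district_grid
    xs = np.linspace(0, config.width_km, gc + 1)
    ys = np.linspace(0, config.height_km, gr + 1)
    districts = []
    did = 0
    for i in range(gr):
        for j in range(gc):
            districts.append((did, box(xs[j], ys[i], xs[j + 1], ys[i + 1])))
            did += 1

    return Landscape(
        bounds=(0.0, 0.0, config.width_km, config.height_km),
        resolution_km=res,
        districts=districts,
        pregnancy_raster=preg_raster,
        covariate_rasters={"ntl": ntl_raster, "travel_time": tt},
        friction_raster=friction_raster,
        facilities=fac,
        roads=roads,
        barriers=barriers,
    )


def simulate_gaussian_field(landscape: Landscape, matern: MaternParams,
                            seed: int = 0) -> GridSurface:
    """One draw of the zero-mean Matérn field on the landscape grid.

    Exact dense simulation: Cholesky of sigma2 * R(phi, nu) with a 1e-8
    relative diagonal jitter.  Grids beyond ~10,000 cells are refused
    (dense factorisation).
    """
    template = landscape.grid_template()
    ncells = template.values.size
    if ncells > 10_500:
        raise ValueError("grid too large for exact dense simulation")
    if matern.sigma2 == 0.0:
        return template.copy_with(np.zeros_like(template.values))
    xc, yc = template.cell_centers()
    pts = np.column_stack([xc.ravel(), yc.ravel()])
    D = squareform(pdist(pts))
    cov = matern.sigma2 * matern_correlation(D, matern.phi, matern.nu)
    cov[np.diag_indices(ncells)] += 1e-8 * matern.sigma2
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "field covariance not positive definite after jitter; "
            "ill-conditioned Matérn parameters") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(ncells)
    return template.copy_with((L @ z).reshape(template.values.shape))


def displace_coordinates(point, urban: bool, district,
                         seed_or_rng, max_km: float | None = None,
                         max_retries: int = 1000):
    """Randomly displace a cluster coordinate within its district.

    Distance is uniform on [0, max] with max 2 km for urban clusters and
    5 km for rural ones, except a Bernoulli(0.01) subset of rural clusters
    displaced up to 10 km; the bearing is uniform.  Candidates outside the
    district are rejected and redrawn; after ``max_retries`` failures the
    original point is returned with a warning.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    px, py = float(point[0]), float(point[1])
    if max_km is None:
        if urban:
            max_km = URBAN_MAX_KM
        else:
            long = rng.uniform() < RURAL_LONG_PROB
            max_km = RURAL_LONG_MAX_KM if long else RURAL_MAX_KM
    if max_km == 0:
        return (px, py)
    for _ in range(max_retries):
        dist = rng.uniform(0.0, max_km)
        bearing = rng.uniform(0.0, 2.0 * np.pi)
        cand = (px + dist * np.cos(bearing), py + dist * np.sin(bearing))
        if district.covers(Point(cand)):
            return cand
    warnings.warn("displacement rejected %d times; keeping original point"
                  % max_retries)
    return (px, py)


def _buffered_or_nearest(raster: GridSurface, point, radius: float) -> float:
    """Buffered mean; falls back to the nearest data cell when the buffer
    holds only nodata (e.g. a cluster sitting on a river)."""
    try:
        return accessibility.extract_buffered_mean(raster, point, radius)
    except ValueError:
        xc, yc = raster.cell_centers()
        ok = raster.mask()
        d2 = (xc - point[0]) ** 2 + (yc - point[1]) ** 2
        d2[~ok] = np.inf
        r, c = np.unravel_index(np.argmin(d2), d2.shape)
        return float(raster.values[r, c])


def _district_of(point, districts) -> int:
    p = Point(point)
    for did, poly in sorted(districts, key=lambda t: t[0]):
        if poly.covers(p):
            return did
    return -1


def simulate_survey(landscape: Landscape, truth: TruthParams,
                    n_clusters: int = 150, n_per_cluster: int = 25,
                    seed: int = 0, urban_quantile: float = 0.75,
                    weight_sd: float = 0.25,
                    education_intercept: float = 1.2,
                    education_slope: float = 0.8) -> SurveyDataset:
    """Simulate a cluster survey from the generative model on the landscape.

    Cluster locations are drawn proportional to pregnancy density; outcomes
    follow Binomial(n, inverse-logit(d'(x) beta + S(x) + Z)).  Covariates
    are recorded as buffered-mean extractions at the *displaced* coordinate
    (radius 2 km urban / 5 km rural), mirroring how satellite covariates
    are attached to real displaced survey clusters; the generative linear
    predictor uses the exact covariate values at the true location.
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    if n_per_cluster < 1:
        raise ValueError("need at least one woman per cluster")
    for name in truth.covariates:
        if name not in landscape.covariate_rasters:
            raise ValueError(f"truth covariate {name!r} not in landscape")

    rng = np.random.default_rng(seed)
    field_seed = int(rng.integers(2 ** 31))
    S = simulate_gaussian_field(
        landscape,
        MaternParams(truth.matern.sigma2, truth.matern.phi,
                     truth.matern.nu, 0.0),
        seed=field_seed)

    preg = landscape.pregnancy_raster
    nrows, ncols = preg.values.shape
    pmass = preg.values.ravel().clip(min=0)
    pmass = pmass / pmass.sum()
    cells = rng.choice(nrows * ncols, size=n_clusters, p=pmass)
    crow, ccol = np.unravel_index(cells, (nrows, ncols))
    res = preg.res
    tx = preg.x0 + (ccol + rng.uniform(size=n_clusters)) * res
    ty = preg.y0 + (nrows - crow - rng.uniform(size=n_clusters)) * res

    ntl_raster = landscape.covariate_rasters["ntl"]
    urban_cut = np.quantile(ntl_raster.values[ntl_raster.mask()],
                            urban_quantile)
    urban = ntl_raster.value_at(tx, ty) >= urban_cut

    rows = []
    for i in range(n_clusters):
        did = _district_of((tx[i], ty[i]), landscape.districts)
        poly = dict(landscape.districts)[did]
        dx, dy = displace_coordinates((tx[i], ty[i]), bool(urban[i]), poly, rng)
        # at least one cell size, else a small buffer can miss every centre
        radius = max(URBAN_MAX_KM if urban[i] else RURAL_MAX_KM,
                     landscape.resolution_km)
        rec = {"cluster_id": i, "x": dx, "y": dy,
               "true_x": tx[i], "true_y": ty[i],
               "urban": int(urban[i]), "district_id": did}
        for name, raster in landscape.covariate_rasters.items():
            rec[name] = _buffered_or_nearest(raster, (dx, dy), radius)
        rows.append(rec)
    df = pd.DataFrame(rows)

    # generative linear predictor at the true locations
    eta = np.full(n_clusters, truth.beta[0])
    for k, name in enumerate(truth.covariates, start=1):
        eta += truth.beta[k] * landscape.covariate_rasters[name].value_at(tx, ty)
    eta += S.value_at(tx, ty)
    z = rng.normal(0.0, np.sqrt(truth.matern.tau2), n_clusters)
    eta += z
    y = rng.binomial(n_per_cluster, expit(eta))

    df["n_women"] = n_per_cluster
    df["n_anc4"] = y
    df["weight"] = np.exp(rng.normal(0.0, weight_sd, n_clusters))

    # strata derived from the recorded covariates
    wealth_cut = np.quantile(df["ntl"], 0.40)   # two poorer quintiles
    df["wealth"] = np.where(df["ntl"] < wealth_cut, "poor", "non-poor")
    df["access"] = np.where(
        df["travel_time"] <= accessibility.ACCESS_CUTOFF_MINUTES,
        "within_1h", "beyond_1h")
    ntl_z = (df["ntl"] - df["ntl"].mean()) / max(df["ntl"].std(ddof=0), 1e-12)
    p_some = expit(education_intercept + education_slope * ntl_z)
    df["education"] = np.where(rng.uniform(size=n_clusters) < p_some,
                               "some", "none")

    covnames = list(dict.fromkeys(list(truth.covariates)
                                  + list(landscape.covariate_rasters)))
    return SurveyDataset(df, covnames)
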