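"""Travel time to the nearest health facility over a friction surface.

A friction raster gives traversal cost in minutes per km.  Road cells
override friction with a speed (km/h); barrier cells (rivers, lakes) are
impassable unless a road crosses them.  Travel time is the multi-source
least-cost path over the 8-connected raster graph, the standard
accessibility-modelling construction.  The ``<= 60 minutes`` rule converts
the surface into the good-access / marginalized equity stratifier.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grids import GridSurface

__all__ = ["CostModel", "travel_time_map", "classify_access",
           "extract_buffered_mean"]

ACCESS_CUTOFF_MINUTES = 60.0


@dataclass
class CostModel:
    """Friction raster plus road overrides and impassable barriers.

    roads maps (row, col) -> speed in km/h; barriers is a set of (row, col).
    A road crossing a barrier cell makes that cell passable at road speed.
    """

    friction: GridSurface
    roads: dict[tuple[int, int], float] = field(default_factory=dict)
    barriers: set[tuple[int, int]] = field(default_factory=set)
    connectivity: int = 8

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.roads.values()):
            raise ValueError("road speeds must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        vals = self.friction.values
        ok = self.friction.mask()
        if (vals[ok] <= 0).any():
            raise ValueError("friction must be positive where not nodata")

    def minutes_per_km(self) -> np.ndarray:
        """Per-cell traversal cost; NaN where impassable."""
        out = np.where(self.friction.mask(), self.friction.values, np.nan)
        for (r, c) in self.barriers:
            out[r, c] = np.nan
        for (r, c), speed in self.roads.items():
            out[r, c] = 60.0 / speed
        return out


def travel_time_map(cost: CostModel, facilities: np.ndarray) -> GridSurface:
    """Minutes to the nearest facility by multi-source least-cost paths.

    Edge cost between neighbouring cells is the mean of their minutes-per-km
    values times the step length (resolution, x sqrt(2) on diagonals).
    Unreachable or impassable cells are nodata.
    """
    grid = cost.friction
    f = cost.minutes_per_km()
    nrows, ncols = f.shape
    passable = np.isfinite(f)
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)

    steps = [(0, 1, 1.0), (1, 0, 1.0)]
    if cost.connectivity == 8:
        steps += [(1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]

    rows_, cols_, wts_ = [], [], []
    for dr, dc, mult in steps:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        a, b = idx[r0, c0].ravel(), idx[r1, c1].ravel()
        fa, fb = f[r0, c0].ravel(), f[r1, c1].ravel()
        ok = np.isfinite(fa) & np.isfinite(fb)
        w = 0.5 * (fa[ok] + fb[ok]) * grid.res * mult
        rows_.append(a[ok])
        cols_.append(b[ok])
        wts_.append(w)
    rows_ = np.concatenate(rows_)
    cols_ = np.concatenate(cols_)
    wts_ = np.concatenate(wts_)
    n = nrows * ncols
    graph = coo_matrix((wts_, (rows_, cols_)), shape=(n, n)).tocsr()

    facilities = np.atleast_2d(np.asarray(facilities, dtype=float))
    frow, fcol = grid.index_of(facilities[:, 0], facilities[:, 1])
    sources = [int(idx[r, c]) for r, c in zip(np.atleast_1d(frow),
                                              np.atleast_1d(fcol))
               if passable[r, c]]
    n_dropped = len(np.atleast_1d(frow)) - len(sources)
    if not sources:
        raise ValueError("all facilities fall on impassable cells")
    if n_dropped:
        warnings.warn(f"{n_dropped} facility(ies) on impassable cells ignored")

    dist = dijkstra(graph, directed=False, indices=sources, min_only=True)
    tt = dist.reshape(nrows, ncols)
    values = np.where(np.isfinite(tt) & passable, tt, grid.nodata)
    return grid.copy_with(values)


def classify_access(tt: GridSurface,
                    cutoff_minutes: float = ACCESS_CUTOFF_MINUTES) -> GridSurface:
    """1 where travel time <= cutoff (good access), else 0 (marginalized).

    Exactly-at-cutoff cells count as good access; nodata (unreachable)
    cells are marginalized.
    """
    ok = tt.mask() & (tt.values <= cutoff_minutes)
    out = tt.copy_with(ok.astype(float))
    out.nodata = -9999.0
    return out


def extract_buffered_mean(surface: GridSurface, point, radius_km: float) -> float:
    """Mean of data cells whose centres lie within radius of the point.

    With radius 0 this is the value of the cell containing the point.  The
    buffered extraction mirrors how satellite covariates are summarised at
    displaced survey-cluster coordinates.
    """
    if radius_km < 0:
        raise ValueError("radius must be non-negative")
    px, py = float(point[0]), float(point[1])
    if radius_km == 0:
        val = float(surface.value_at(px, py))
        if val == surface.nodata:
            raise ValueError("cell at point is nodata")
        return val
    xc, yc = surface.cell_centers()
    within = (xc - px) ** 2 + (yc - py) ** 2 <= radius_km ** 2
    sel = within & surface.mask()
    if not sel.any():
        raise ValueError("no data cells within buffer")
    return float(surface.values[sel].mean())
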