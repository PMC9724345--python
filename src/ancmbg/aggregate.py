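"""Population-weighted district aggregation and headcounts.

District coverage for each posterior draw is the pregnancy-weighted mean
of cell coverage over the cells whose centres fall in the district; the
district exceedance probability is the fraction of draws whose aggregated
coverage clears the target.  Headcounts multiply the draw-wise mean
coverage by the district's pregnancy total, so women with and without
ANC4+ always sum exactly to the total.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridSurface
from .predict import PosteriorSamples
from .regions import assign_cells

__all__ = ["DistrictSummary", "district_aggregate", "resample_to_grid",
           "summaries_to_frame"]


@dataclass
class DistrictSummary:
    district_id: int
    coverage_mean: float
    coverage_lower95: float
    coverage_upper95: float
    exceedance_probability: float
    pregnant_women_total: float
    women_with_anc4: float
    women_without_anc4: float
    pixel_count: int


def summaries_to_frame(summaries: list[DistrictSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def district_aggregate(samples: PosteriorSamples, pregnancies: GridSurface,
                       districts: list[tuple[int, object]],
                       threshold: float | None = None) -> list[DistrictSummary]:
    """Aggregate the coverage draws over district polygons.

    Requires the pregnancy raster to be co-registered with the prediction
    grid (resample first if not).  Districts with zero pregnancies in
    their cells get NaN coverage and zero headcounts.
    """
    t = samples.threshold_default if threshold is None else float(threshold)
    if not samples.template.same_geometry(pregnancies):
        raise ValueError("pregnancy raster not co-registered with the "
                         "prediction grid; resample_to_grid first")

    labels = assign_cells(samples.template, districts)
    cell_labels = labels[samples.cell_index[:, 0], samples.cell_index[:, 1]]
    preg_cells = pregnancies.values[samples.cell_index[:, 0],
                                    samples.cell_index[:, 1]]
    preg_cells = np.where(preg_cells == pregnancies.nodata, 0.0, preg_cells)

    out: list[DistrictSummary] = []
    for did, _poly in sorted(districts, key=lambda d: d[0]):
        sel = cell_labels == did
        total = float(preg_cells[sel].sum())
        npix = int(sel.sum())
        if npix == 0 or total <= 0:
            out.append(DistrictSummary(did, np.nan, np.nan, np.nan, np.nan,
                                       total, 0.0, 0.0, npix))
            continue
        w = preg_cells[sel] / total
        draws = samples.samples[:, sel] @ w          # draw-wise coverage
        mean = float(draws.mean())
        lo, hi = np.percentile(draws, [2.5, 97.5])
        ep = float((draws > t).mean())
        with_anc4 = mean * total
        out.append(DistrictSummary(did, mean, float(lo), float(hi), ep,
                                   total, with_anc4, total - with_anc4, npix))
    return out


def resample_to_grid(surface: GridSurface, template: GridSurface,
                     mode: str = "sum") -> GridSurface:
    """Re-grid a raster onto a template by cell-centre assignment.

    mode "sum" conserves totals (count rasters, e.g. pregnancies); mode
    "mean" averages the contributing source cells (intensity rasters).
    Source nodata cells are skipped; template cells receiving nothing are
    nodata.
    """
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    sb, tb = surface.bounds, template.bounds
    if sb[2] <= tb[0] or tb[2] <= sb[0] or sb[3] <= tb[1] or tb[3] <= sb[1]:
        raise ValueError("surface and template extents do not overlap")
    if surface.same_geometry(template):
        return template.copy_with(surface.values.copy())

    xc, yc = surface.cell_centers()
    ok = surface.mask()
    inside = (ok & (xc >= tb[0]) & (xc < tb[2])
              & (yc >= tb[1]) & (yc < tb[3]))
    row, col = template.index_of(xc[inside], yc[inside])
    flat = row * template.ncols + col
    vals = surface.values[inside]
    size = template.nrows * template.ncols
    sums = np.bincount(flat, weights=vals, minlength=size)
    counts = np.bincount(flat, minlength=size)
    if mode == "sum":
        out = np.where(counts > 0, sums, template.nodata)
    else:
        out = np.where(counts > 0, sums / np.maximum(counts, 1),
                       template.nodata)
    return template.copy_with(out.reshape(template.nrows, template.ncols))
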