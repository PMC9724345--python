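"""District polygons: GeoJSON interchange and raster-cell assignment."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape

from .grids import GridSurface

__all__ = ["write_districts", "read_districts", "assign_cells"]


def write_districts(path: str | Path, districts: list[tuple[int, object]]) -> None:
    """Write [(district_id, shapely polygon), ...] as a GeoJSON FeatureCollection."""
    features = [
        {"type": "Feature",
         "properties": {"district_id": int(did)},
         "geometry": mapping(poly)}
        for did, poly in districts
    ]
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload))


def read_districts(path: str | Path) -> list[tuple[int, object]]:
    payload = json.loads(Path(path).read_text())
    return [(int(f["properties"]["district_id"]), shape(f["geometry"]))
            for f in payload["features"]]


def assign_cells(grid: GridSurface,
                 districts: list[tuple[int, object]]) -> np.ndarray:
    """District id per grid cell by the cell-centre rule, -1 where none.

    A centre on a shared boundary is assigned to the district with the
    lower id (districts are scanned in increasing id order and a cell is
    never reassigned).
    """
    import shapely

    xc, yc = grid.cell_centers()
    out = np.full(grid.values.shape, -1, dtype=int)
    pts = shapely.points(np.column_stack([xc.ravel(), yc.ravel()]))
    flat = out.ravel()
    for did, poly in sorted(districts, key=lambda t: t[0]):
        free = flat == -1
        if not free.any():
            break
        hit = shapely.covers(poly, pts)
        flat[free & hit] = did
    return flat.reshape(out.shape)
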