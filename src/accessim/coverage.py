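"""Zonal travel-time statistics and population-weighted geographic coverage.

Coverage is the percentage of women of childbearing age (WoCBA) living
within a travel-time threshold (30/60/120 minutes by default) of the nearest
facility of a stratum.  Unreachable populated cells stay in the denominator:
coverage is a claim about all women, not only those with a path to care.
Cells belong to the zone containing their centre, so zones at one level
partition the grid and covered population aggregates consistently.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import shapely

from .grid import Raster
from .vectors import ZonePolygons

__all__ = ["mask_populated", "zone_index_raster", "zonal_stats", "coverage"]

DEFAULT_THRESHOLDS = (30.0, 60.0, 120.0)


def mask_populated(tt: Raster, pop: Raster, min_pop: float = 0.0) -> Raster:
    """Constrain a travel-time surface to populated cells.

    Cells whose WoCBA count is not strictly above ``min_pop`` become NaN;
    idempotent for a fixed population raster.
    """
    tt.grid.require_same(pop.grid, ("travel time", "population"))
    out = tt.copy()
    out.data = np.asarray(out.data, float).copy()
    out.data[~(np.asarray(pop.data, float) > min_pop)] = np.nan
    return out


def zone_index_raster(zones: ZonePolygons, level: str, grid) -> Raster:
    """Assign each cell (by centre) to a zone at one level; -1 = no zone.

    When zone polygons overlap or share a boundary through a cell centre,
    the zone with the lexicographically smallest zone_id wins, so the
    assignment is an exact partition.
    """
    zs = sorted(zones.at_level(level), key=lambda z: z.zone_id)
    if not zs:
        raise ValueError(f"no zones at level {level!r}")
    X, Y = grid.center_mesh()
    pts = shapely.points(X.ravel(), Y.ravel())
    out = np.full(grid.shape[0] * grid.shape[1], -1, dtype=np.int32)
    for i in range(len(zs) - 1, -1, -1):  # lowest id painted last -> wins ties
        inside = shapely.covers(zs[i].polygon, pts)
        out[inside] = i
    return Raster(grid, out.reshape(grid.shape), meta={"level": level,
                  "zone_ids": [z.zone_id for z in zs]})


def _zone_iter(zones: ZonePolygons, grid, levels: Optional[Sequence[str]]):
    for level in (levels or zones.levels()):
        zr = zone_index_raster(zones, level, grid)
        ids = zr.meta["zone_ids"]
        for i, zid in enumerate(ids):
            yield level, zid, (zr.data == i)


def zonal_stats(
    tt: Raster,
    zones: ZonePolygons,
    pop: Raster,
    levels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-zone travel-time summaries over populated, reachable cells.

    Emits both the unweighted (area-style) mean over populated cells and a
    WoCBA-weighted mean; zones without contributing cells get n_cells 0 and
    NaN statistics.
    """
    tt.grid.require_same(pop.grid, ("travel time", "population"))
    vals = np.asarray(tt.data, float)
    w = np.asarray(pop.data, float)
    contributing = np.isfinite(vals) & (w > 0)
    rows: List[dict] = []
    for level, zid, inzone in _zone_iter(zones, tt.grid, levels):
        m = inzone & contributing
        n = int(m.sum())
        if n == 0:
            stats = dict(mean_tt=np.nan, min_tt=np.nan, max_tt=np.nan,
                         pop_weighted_mean_tt=np.nan)
        else:
            v = vals[m]
            stats = dict(
                mean_tt=float(v.mean()),
                min_tt=float(v.min()),
                max_tt=float(v.max()),
                pop_weighted_mean_tt=float(np.average(v, weights=w[m])),
            )
        rows.append(
            dict(zone_id=zid, zone_level=level,
                 stratum=tt.meta.get("stratum"), scenario=tt.meta.get("scenario"),
                 n_cells=n, **stats)
        )
    return pd.DataFrame(rows)


def coverage(
    tt: Raster,
    pop: Raster,
    zones: ZonePolygons,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    levels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Percent of WoCBA within each travel-time threshold, per zone.

    pct = 100 * sum(wocba | tt <= T) / sum(wocba in zone); unreachable cells
    count in the denominator only.  Zones with zero population report NaN
    (undefined), never 0.
    """
    tt.grid.require_same(pop.grid, ("travel time", "population"))
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds) or sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be positive and sorted ascending")
    vals = np.asarray(tt.data, float)
    w = np.asarray(pop.data, float)
    rows: List[dict] = []
    for level, zid, inzone in _zone_iter(zones, tt.grid, levels):
        total = float(w[inzone].sum())
        for T in thresholds:
            if total <= 0:
                covered, pct = np.nan, np.nan
            else:
                covered = float(w[inzone & np.isfinite(vals) & (vals <= T)].sum())
                pct = 100.0 * covered / total
            rows.append(
                dict(zone_id=zid, zone_level=level,
                     stratum=tt.meta.get("stratum"), scenario=tt.meta.get("scenario"),
                     threshold=float(T), pct_wocba=pct,
                     wocba_covered=covered, wocba_total=total)
            )
    return pd.DataFrame(rows)
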