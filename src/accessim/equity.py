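"""Wealth- and urbanicity-related inequality in travel time.

Each populated grid cell is matched to the nearest relative wealth index
(RWI) point estimate, cells are ranked by RWI, and population-weighted
quintiles are formed so each quintile holds an equal share of women (not of
cells).  The equiplot summary reports the WoCBA-weighted mean (and median)
travel time per quintile, for the study area and each département — the
per-geography dot rows of an equiplot.  The urbanicity summary reports the
weighted mean travel time per settlement band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .coverage import zone_index_raster
from .grid import Raster
from .vectors import RwiPoints, ZonePolygons

__all__ = [
    "match_rwi",
    "QuintileAssignment",
    "assign_quintiles",
    "equiplot_table",
    "urbanicity_summary",
    "weighted_median",
    "plot_equiplot",
]


def match_rwi(tt: Raster, rwi: RwiPoints) -> Raster:
    """Nearest-point RWI value for every cell (Euclidean, cell centres).

    Distance ties (within 1e-9 m) resolve to the lowest point index.
    """
    if len(rwi) == 0:
        raise ValueError("RWI point set is empty")
    X, Y = tt.grid.center_mesh()
    cells = np.column_stack([X.ravel(), Y.ravel()])
    pts = np.column_stack([rwi.x, rwi.y])
    tree = cKDTree(pts)
    d, i = tree.query(cells)
    # enforce the lowest-index tie rule, which KDTree does not guarantee
    ties = tree.query_ball_point(cells, d + 1e-9)
    idx = np.array([min(t) if t else j for t, j in zip(ties, i)])
    return Raster(tt.grid, rwi.rwi[idx].reshape(tt.grid.shape))


@dataclass
class QuintileAssignment:
    """Per-cell wealth quintile (1 = poorest ... 5 = richest) with weights."""

    rwi: np.ndarray       # matched rwi value per cell (flat)
    quintile: np.ndarray  # 1..5 per cell, 0 where weight is 0 (unassigned)
    weight: np.ndarray    # wocba per cell
    shape: tuple

    def quintile_raster(self, grid) -> Raster:
        return Raster(grid, self.quintile.reshape(self.shape).astype(np.int16) - 1)


def assign_quintiles(values: np.ndarray, weights: np.ndarray) -> QuintileAssignment:
    """Population-weighted wealth quintiles.

    Cells are sorted by RWI ascending (stable, so equal-RWI cells stay
    contiguous); a cell's quintile is the one containing the midpoint of its
    cumulative-weight span, so each quintile carries ~20% of total weight,
    off by at most one cell's weight.  Zero-weight cells are unassigned (0).
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have the same shape")
    shape = values.shape
    v = values.ravel()
    w = weights.ravel()
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("all weights are zero; quintiles are undefined")
    q = np.zeros(v.shape, dtype=np.int8)
    active = w > 0
    order = np.argsort(v[active], kind="stable")
    wa = w[active][order]
    cum = np.cumsum(wa)
    mid = cum - wa / 2.0
    # midpoint exactly on a quintile boundary rounds up to the next quintile
    qa = np.minimum((mid / total * 5).astype(int), 4) + 1
    tmp = np.zeros(active.sum(), dtype=np.int8)
    tmp[order] = qa
    q[active] = tmp
    return QuintileAssignment(rwi=v, quintile=q, weight=w, shape=shape)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median: smallest value whose cumulative weight reaches half."""
    order = np.argsort(values, kind="stable")
    cw = np.cumsum(weights[order])
    return float(values[order][np.searchsorted(cw, cw[-1] / 2.0)])


def equiplot_table(
    tt: Raster,
    assignment: QuintileAssignment,
    zones: Optional[ZonePolygons] = None,
    levels: Sequence[str] = ("study_area", "departement"),
) -> pd.DataFrame:
    """WoCBA-weighted mean (and median) travel time per wealth quintile.

    One row per (zone, quintile); five rows per zone, NaN where a quintile
    has no populated reachable cells inside the zone.  Without zones, a
    single 'study_area' geography covering the whole grid is used.
    """
    vals = np.asarray(tt.data, float).ravel()
    q = assignment.quintile
    w = assignment.weight
    if vals.shape != q.shape:
        raise ValueError("assignment and travel time must share the grid")

    geographies: List[tuple] = []
    if zones is None or not any(zones.at_level(lv) for lv in levels):
        geographies.append(("study_area", "study_area", np.ones(vals.shape, bool)))
    else:
        for lv in levels:
            zs = zones.at_level(lv)
            if not zs:
                continue
            zr = zone_index_raster(zones, lv, tt.grid)
            for i, zid in enumerate(zr.meta["zone_ids"]):
                geographies.append((zid, lv, (zr.data == i).ravel()))

    usable = np.isfinite(vals) & (w > 0)
    rows: List[dict] = []
    for zid, lv, inzone in geographies:
        for k in range(1, 6):
            m = usable & inzone & (q == k)
            if not m.any():
                rows.append(dict(zone_id=zid, zone_level=lv,
                                 stratum=tt.meta.get("stratum"),
                                 scenario=tt.meta.get("scenario"),
                                 quintile=k, mean_tt=np.nan, median_tt=np.nan,
                                 wocba=0.0))
                continue
            rows.append(
                dict(zone_id=zid, zone_level=lv,
                     stratum=tt.meta.get("stratum"),
                     scenario=tt.meta.get("scenario"),
                     quintile=k,
                     mean_tt=float(np.average(vals[m], weights=w[m])),
                     median_tt=weighted_median(vals[m], w[m]),
                     wocba=float(w[m].sum()))
            )
    return pd.DataFrame(rows)


def plot_equiplot(table: pd.DataFrame, path=None, value="mean_tt"):
    """Dot-per-quintile equiplot, one row per geography.

    Dots along a horizontal line show the per-quintile travel-time summary;
    the line length is the poorest-richest gap.  Saves to ``path`` (SVG/PNG
    by extension) when given, else returns the matplotlib figure.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    zones = list(dict.fromkeys(table["zone_id"]))
    fig, ax = plt.subplots(figsize=(7, 0.8 * len(zones) + 1.2))
    cmap = plt.get_cmap("viridis")
    for yi, zid in enumerate(zones):
        sub = table[table["zone_id"] == zid].sort_values("quintile")
        vals = sub[value].to_numpy(float)
        ok = np.isfinite(vals)
        ax.plot(vals[ok], np.full(ok.sum(), yi), "-", color="0.7", zorder=1)
        for q, v in zip(sub["quintile"][ok], vals[ok]):
            ax.scatter(v, yi, color=cmap((q - 1) / 4), s=60, zorder=2,
                       label=f"Q{q}" if yi == 0 else None)
    ax.set_yticks(range(len(zones)), zones)
    ax.set_xlabel("travel time (minutes)")
    ax.legend(title="wealth quintile\n(1 = poorest)", loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
        return None
    return fig


def urbanicity_summary(
    tt: Raster, urbanicity: Raster, pop: Raster
) -> pd.DataFrame:
    """WoCBA-weighted mean travel time per urbanicity band.

    Every band present in the raster appears once; bands with no populated
    reachable cells report NaN.
    """
    tt.grid.require_same(urbanicity.grid, ("travel time", "urbanicity"))
    tt.grid.require_same(pop.grid, ("travel time", "population"))
    vals = np.asarray(tt.data, float)
    bands = np.asarray(urbanicity.data)
    w = np.asarray(pop.data, float)
    usable = np.isfinite(vals) & (w > 0)
    band_names = urbanicity.meta.get("band_names")
    rows: List[dict] = []
    for b in np.unique(bands[bands >= 0]):
        m = usable & (bands == b)
        rows.append(
            dict(band=int(b),
                 band_name=(band_names[int(b)] if band_names else str(int(b))),
                 stratum=tt.meta.get("stratum"), scenario=tt.meta.get("scenario"),
                 mean_tt=float(np.average(vals[m], weights=w[m])) if m.any() else np.nan,
                 wocba=float(w[m].sum()))
        )
    return pd.DataFrame(rows)
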