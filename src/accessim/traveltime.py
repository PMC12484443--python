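"""Multi-source least-cost travel-time accumulation on the friction grid.

Every grid cell gets the minimum cumulative traversal time (minutes) to the
nearest facility of a stratum, under one speed scenario.  The computation is
a multi-source Dijkstra over the lattice graph: cells are nodes, moves to
the 8 (or 16, adding knight moves) neighbours are edges, and a move from
cell a to cell b costs

    d * (0.5 / v_a + 0.5 / v_b)

with d the move length (cell, cell*sqrt(2), cell*sqrt(5)) and v the cell
speed — slope-adjusted in the direction of travel on walking cells.  The
half-cell form makes a road/off-road boundary move cost the mean of the two
regimes.  Cells separated from every facility by zero-speed (water) cells
are unreachable and reported as +inf.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .classes import PUBLIC_SECTORS, SCENARIOS, STRATA
from .friction import SpeedRaster, build_speed_raster, rasterize_roads, slope_factor
from .grid import GridSpec, Raster
from .speeds import SpeedTable
from .vectors import FacilityRegistry, RoadNetwork

logger = logging.getLogger(__name__)

__all__ = ["select_stratum", "accumulate", "run_matrix", "neighbour_offsets"]

_OFFSETS_8 = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)]
_OFFSETS_16 = _OFFSETS_8 + [
    (1, 2), (2, 1), (-1, 2), (-2, 1), (1, -2), (2, -1), (-1, -2), (-2, -1),
]


def neighbour_offsets(connectivity: int) -> List[Tuple[int, int]]:
    if connectivity == 8:
        return list(_OFFSETS_8)
    if connectivity == 16:
        return list(_OFFSETS_16)
    raise ValueError("connectivity must be 8 or 16")


def select_stratum(registry: FacilityRegistry, stratum: str) -> FacilityRegistry:
    """Filter the registry to one of the four analysis strata.

    all -> identity; public -> government + faith-based sectors;
    hospitals -> hospital level; public_hospitals -> both filters.
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
    t = registry.table
    keep = np.ones(len(t), bool)
    if stratum in ("public", "public_hospitals"):
        keep &= t["sector"].isin(PUBLIC_SECTORS).to_numpy()
    if stratum in ("hospitals", "public_hospitals"):
        keep &= (t["level"] == "hospital").to_numpy()
    if not keep.any():
        raise ValueError(f"stratum {stratum!r} selects no facilities (no sources)")
    return FacilityRegistry(t[keep].reset_index(drop=True))


def _snap_sources(
    speed: SpeedRaster, xy: np.ndarray, snap_radius: int = 3
) -> List[Tuple[int, int]]:
    """Map facility points to passable cells.

    A facility takes its containing cell; if that cell is a barrier it snaps
    to the nearest passable cell within ``snap_radius`` cells, else it is
    dropped with a warning.
    """
    spec = speed.grid
    cells: List[Tuple[int, int]] = []
    offs = [
        (dr, dc)
        for dr in range(-snap_radius, snap_radius + 1)
        for dc in range(-snap_radius, snap_radius + 1)
    ]
    offs.sort(key=lambda o: (o[0] * o[0] + o[1] * o[1], o))
    n_outside = n_dropped = n_snapped = 0
    for x, y in xy:
        if not spec.contains(x, y):
            logger.debug("facility at (%.1f, %.1f) outside grid; dropped", x, y)
            n_outside += 1
            continue
        r, c = spec.cell_of(x, y)
        r, c = int(r), int(c)
        snapped = None
        for dr, dc in offs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < spec.n_rows and 0 <= cc < spec.n_cols and speed.speed[rr, cc] > 0:
                snapped = (rr, cc)
                break
        if snapped is None:
            logger.debug(
                "facility at (%.1f, %.1f) on a barrier with no passable cell "
                "within %d cells; dropped", x, y, snap_radius,
            )
            n_dropped += 1
            continue
        if snapped != (r, c):
            logger.debug(
                "facility at (%.1f, %.1f) snapped from barrier cell %s to %s",
                x, y, (r, c), snapped,
            )
            n_snapped += 1
        cells.append(snapped)
    if n_outside or n_dropped or n_snapped:
        logger.warning(
            "facility snapping: %d outside grid (dropped), %d on barriers with "
            "no passable cell within %d cells (dropped), %d snapped to a "
            "nearby passable cell", n_outside, n_dropped, snap_radius, n_snapped,
        )
    return cells


def _move_graph(
    speed: SpeedRaster, dem: Optional[Raster], connectivity: int
) -> csr_matrix:
    """Directed sparse graph of per-move traversal times in seconds."""
    spec = speed.grid
    n_rows, n_cols = spec.shape
    n = n_rows * n_cols
    v = speed.speed
    walking = speed.is_walking
    elev = None
    if dem is not None:
        spec.require_same(dem.grid, ("speed raster", "DEM"))
        elev = np.asarray(dem.data, float)

    rows_i: List[np.ndarray] = []
    cols_i: List[np.ndarray] = []
    costs: List[np.ndarray] = []
    for dr, dc in neighbour_offsets(connectivity):
        d = spec.cell_size * float(np.hypot(dr, dc))
        r_lo, r_hi = max(0, -dr), min(n_rows, n_rows - dr)
        c_lo, c_hi = max(0, -dc), min(n_cols, n_cols - dc)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        va = v[r_lo:r_hi, c_lo:c_hi]
        vb = v[r_lo + dr : r_hi + dr, c_lo + dc : c_hi + dc]
        ok = (va > 0) & (vb > 0)
        if not ok.any():
            continue
        if elev is not None:
            slope = (elev[r_lo + dr : r_hi + dr, c_lo + dc : c_hi + dc]
                     - elev[r_lo:r_hi, c_lo:c_hi]) / d
        else:
            slope = np.zeros_like(va)
        fac = slope_factor(slope)
        va_eff = np.where(walking[r_lo:r_hi, c_lo:c_hi], va * fac, va)
        vb_eff = np.where(
            walking[r_lo + dr : r_hi + dr, c_lo + dc : c_hi + dc], vb * fac, vb
        )
        cost = d * (0.5 / np.where(ok, va_eff, 1.0) + 0.5 / np.where(ok, vb_eff, 1.0))
        rr, cc = np.nonzero(ok)
        a = (rr + r_lo) * n_cols + (cc + c_lo)
        b = (rr + r_lo + dr) * n_cols + (cc + c_lo + dc)
        rows_i.append(a)
        cols_i.append(b)
        costs.append(cost[ok])
    if rows_i:
        data = np.concatenate(costs)
        return csr_matrix(
            (data, (np.concatenate(rows_i), np.concatenate(cols_i))), shape=(n, n)
        )
    return csr_matrix((n, n))


def accumulate(
    speed: SpeedRaster,
    dem: Optional[Raster],
    sources: FacilityRegistry | np.ndarray,
    connectivity: int = 8,
    stratum: str = "all",
    scenario: str = "average",
) -> Raster:
    """Travel-time surface (minutes) from every cell to the nearest source.

    ``sources`` is a FacilityRegistry or an (n, 2) array of planar (x, y).
    Returns a Raster whose data holds minutes (0 at sources, +inf where
    unreachable) with metadata keys stratum/scenario/connectivity.
    """
    xy = sources.xy if isinstance(sources, FacilityRegistry) else np.atleast_2d(sources)
    if len(xy) == 0:
        raise ValueError("at least one source facility is required")
    cells = _snap_sources(speed, np.asarray(xy, float))
    if not cells:
        raise ValueError("no source lies on or near a passable cell")
    graph = _move_graph(speed, dem, connectivity)
    idx = np.unique([r * speed.grid.n_cols + c for r, c in cells])
    # costs are per-move seconds; travel population->facility equals
    # facility->population when per-move costs are symmetric, so expanding
    # from the facilities uses the transpose of the directed move graph
    seconds = dijkstra(graph.T, directed=True, indices=idx, min_only=True)
    minutes = (seconds / 60.0).reshape(speed.grid.shape)
    return Raster(
        speed.grid,
        minutes,
        meta={"stratum": stratum, "scenario": scenario, "connectivity": connectivity},
    )


def run_matrix(
    roads: RoadNetwork,
    landcover: Raster,
    dem: Optional[Raster],
    table: SpeedTable,
    registry: FacilityRegistry,
    strata: Sequence[str] = STRATA,
    scenarios: Sequence[str] = SCENARIOS,
    connectivity: int = 8,
) -> Dict[Tuple[str, str], Raster]:
    """Travel-time surfaces for every (facility stratum, speed scenario) pair.

    The full design — four strata by three scenarios — yields 12 surfaces,
    each independently reproducible from its inputs.
    """
    if not strata or not scenarios:
        raise ValueError("strata and scenarios must be non-empty")
    road_raster = rasterize_roads(roads, landcover.grid, table)
    out: Dict[Tuple[str, str], Raster] = {}
    for scenario in scenarios:
        speed = build_speed_raster(road_raster, landcover, table, scenario)
        for stratum in strata:
            sub = select_stratum(registry, stratum)
            out[(stratum, scenario)] = accumulate(
                speed, dem, sub, connectivity, stratum=stratum, scenario=scenario
            )
    return out
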