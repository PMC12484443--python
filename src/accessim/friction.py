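"""Merged friction surface: per-cell traversal speed from roads + land cover.

Roads override land cover wherever a segment crosses a cell (supercover
rasterization: a cell is painted when the segment touches any part of it, so
thin diagonal roads stay connected on the grid).  Off-road cells take the
land-cover walking speed; open water has speed 0 and acts as an absolute
barrier.  Walking speeds are adjusted for terrain slope at move time using a
normalized Tobler hiking function, so the tabled walking speeds are
flat-ground speeds; motorized speeds were observed on real terrain and are
not slope-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import LineString

from .classes import (
    LANDCOVER_NAMES,
    ROAD_CLASSES,
    SCENARIOS,
    WALKING_ROAD_CLASSES,
    WATER_CODE,
)
from .grid import GridSpec, Raster
from .speeds import MS_TO_KMH, SpeedTable
from .vectors import RoadNetwork

__all__ = ["SpeedRaster", "rasterize_roads", "build_speed_raster", "slope_factor"]

#: Tobler hiking function decay; the factor is normalized to 1 on flat ground.
_TOBLER_DECAY = 3.5
_TOBLER_OFFSET = 0.05
_FLAT_NORM = np.exp(-_TOBLER_DECAY * _TOBLER_OFFSET)


@dataclass
class SpeedRaster:
    """Per-cell traversal speed (m/s; 0 = barrier) plus the walking mask.

    ``is_walking`` is True where movement is pedestrian — land-cover cells
    and pedestrian-only ("others") road cells — and marks where the slope
    adjustment applies.
    """

    grid: GridSpec
    speed: np.ndarray  # m/s
    is_walking: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, float)
        self.is_walking = np.asarray(self.is_walking, bool)
        if self.speed.shape != self.grid.shape or self.is_walking.shape != self.grid.shape:
            raise ValueError("speed/is_walking shape must match the grid")
        if not np.all(np.isfinite(self.speed)) or (self.speed < 0).any():
            raise ValueError("speeds must be finite and nonnegative")


def rasterize_roads(
    roads: RoadNetwork, spec: GridSpec, table: SpeedTable | None = None
) -> Raster:
    """Burn road classes onto the grid (supercover).

    Every cell whose area or boundary is touched by a segment carries that
    segment's class; where several classes cross one cell, the class with
    the higher mean speed wins.  Returns an integer raster of indices into
    ``ROAD_CLASSES`` with -1 for road-free cells.
    """
    from .speeds import default_speed_table

    if table is None:
        table = default_speed_table()
    out = np.full(spec.shape, -1, dtype=np.int16)
    if len(roads) == 0:
        return Raster(spec, out)

    # paint slower classes first so faster classes overwrite on conflict
    def class_mean(s):
        return table.speed_kmh("road", s.road_class, "average")

    cs = spec.cell_size
    x0, y0, _, _ = spec.extent
    for seg in sorted(roads.segments, key=lambda s: (class_mean(s), s.segment_id)):
        code = ROAD_CLASSES.index(seg.road_class)
        pts = np.asarray(seg.coords, float)
        for (xa, ya), (xb, yb) in zip(pts[:-1], pts[1:]):
            piece = LineString([(xa, ya), (xb, yb)])
            c_lo = int(np.floor((min(xa, xb) - x0) / cs))
            c_hi = int(np.floor((max(xa, xb) - x0) / cs))
            r_lo = int(np.floor((min(ya, yb) - y0) / cs))
            r_hi = int(np.floor((max(ya, yb) - y0) / cs))
            c_lo, c_hi = max(c_lo, 0), min(c_hi, spec.n_cols - 1)
            r_lo, r_hi = max(r_lo, 0), min(r_hi, spec.n_rows - 1)
            if c_lo > c_hi or r_lo > r_hi:
                continue
            cols = np.arange(c_lo, c_hi + 1)
            rows_b = np.arange(r_lo, r_hi + 1)  # from-bottom index
            cc, rr = np.meshgrid(cols, rows_b)
            boxes = shapely.box(
                x0 + cc.ravel() * cs,
                y0 + rr.ravel() * cs,
                x0 + (cc.ravel() + 1) * cs,
                y0 + (rr.ravel() + 1) * cs,
            )
            hit = shapely.intersects(boxes, piece)
            rows_top = spec.n_rows - 1 - rr.ravel()[hit]
            out[rows_top, cc.ravel()[hit]] = code
    return Raster(spec, out)


def build_speed_raster(
    road_raster: Raster,
    landcover: Raster,
    table: SpeedTable,
    scenario: str,
) -> SpeedRaster:
    """Merge road and land-cover speeds for one scenario into a SpeedRaster.

    Road cells take the road class's scenario speed (walking mask False,
    except pedestrian-only "others" roads); other cells take the land-cover
    scenario speed with walking mask True.  Water stays 0 in every scenario.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    road_raster.grid.require_same(landcover.grid, ("road raster", "land cover"))
    spec = road_raster.grid
    lc = np.asarray(landcover.data)
    rd = np.asarray(road_raster.data)

    lc_codes = np.unique(lc[lc >= 0])
    unknown = [int(c) for c in lc_codes if int(c) not in LANDCOVER_NAMES]
    if unknown:
        raise ValueError(f"unknown land-cover code(s) {unknown}")
    bad_road = np.unique(rd[(rd < -1) | (rd >= len(ROAD_CLASSES))])
    if len(bad_road):
        raise ValueError(f"unknown road code(s) {bad_road.tolist()}")

    speed = np.zeros(spec.shape, float)
    walking = np.ones(spec.shape, bool)
    for code in lc_codes:
        name = LANDCOVER_NAMES[int(code)]
        if not table.has("landcover", name):
            raise ValueError(f"land-cover class {name!r} missing from speed table")
        speed[lc == code] = table.speed_kmh("landcover", name, scenario) / MS_TO_KMH
    for code in np.unique(rd[rd >= 0]):
        name = ROAD_CLASSES[int(code)]
        if not table.has("road", name):
            raise ValueError(f"road class {name!r} missing from speed table")
        mask = rd == code
        speed[mask] = table.speed_kmh("road", name, scenario) / MS_TO_KMH
        walking[mask] = name in WALKING_ROAD_CLASSES
    # water is an absolute barrier in every scenario; bridges are not modelled
    speed[lc == WATER_CODE] = 0.0
    return SpeedRaster(spec, speed, walking)


def slope_factor(slope) -> np.ndarray:
    """Multiplicative walking-speed factor for a signed slope (rise/run).

    Normalized Tobler hiking function:
    ``exp(-3.5 * |s + 0.05|) / exp(-3.5 * 0.05)`` — equal to 1 on flat
    ground, maximized (~1.19) at a gentle -5% descent, and strictly
    decreasing in ``|s + 0.05|``.  Applied only to walking cells; motorized
    travel ignores slope.
    """
    s = np.asarray(slope, float)
    if not np.all(np.isfinite(s)):
        raise ValueError("slope must be finite")
    if np.any(np.abs(s) >= 10):
        raise ValueError("slope magnitude out of sane range (>= 10 rise/run)")
    return np.exp(-_TOBLER_DECAY * np.abs(s + _TOBLER_OFFSET)) / _FLAT_NORM
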