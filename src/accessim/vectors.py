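"""Vector domain types: road network, facility registry, zones, RWI points,
GPS trajectories.

All coordinates are planar metres in the same CRS as the analysis grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

from .classes import (
    FACILITY_LEVELS,
    FACILITY_SECTORS,
    PUBLIC_SECTORS,
    ROAD_CLASSES,
    ZONE_LEVELS,
)

__all__ = [
    "RoadSegment",
    "RoadNetwork",
    "FacilityRegistry",
    "Zone",
    "ZonePolygons",
    "RwiPoints",
    "Trajectory",
]


@dataclass(frozen=True)
class RoadSegment:
    """A classed polyline with at least two vertices."""

    segment_id: int
    road_class: str
    coords: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.road_class not in ROAD_CLASSES:
            raise ValueError(f"unknown road class {self.road_class!r}")
        if len(self.coords) < 2:
            raise ValueError("a road segment needs at least two vertices")

    @property
    def geometry(self) -> LineString:
        return LineString(self.coords)

    @property
    def length(self) -> float:
        return self.geometry.length


@dataclass
class RoadNetwork:
    segments: List[RoadSegment]

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def classes_present(self) -> set:
        return {s.road_class for s in self.segments}

    def geometries(self) -> List[LineString]:
        return [s.geometry for s in self.segments]


@dataclass
class FacilityRegistry:
    """Facility points with level and sector, backed by a DataFrame with
    columns facility_id, x, y, level, sector."""

    table: pd.DataFrame

    REQUIRED = ("facility_id", "x", "y", "level", "sector")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"facility table missing columns {missing}")
        bad_level = set(self.table["level"]) - set(FACILITY_LEVELS)
        bad_sector = set(self.table["sector"]) - set(FACILITY_SECTORS)
        if bad_level:
            raise ValueError(f"unknown facility levels {sorted(bad_level)}")
        if bad_sector:
            raise ValueError(f"unknown facility sectors {sorted(bad_sector)}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def xy(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(float)

    def n_public(self) -> int:
        return int(self.table["sector"].isin(PUBLIC_SECTORS).sum())

    def n_private(self) -> int:
        return int((self.table["sector"] == "private").sum())


@dataclass(frozen=True)
class Zone:
    zone_id: str
    zone_level: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if self.zone_level not in ZONE_LEVELS:
            raise ValueError(f"unknown zone level {self.zone_level!r}")


@dataclass
class ZonePolygons:
    zones: List[Zone]

    def __post_init__(self) -> None:
        for level in {z.zone_level for z in self.zones}:
            ids = [z.zone_id for z in self.zones if z.zone_level == level]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate zone_ids at level {level!r}")

    def at_level(self, level: str) -> List[Zone]:
        return [z for z in self.zones if z.zone_level == level]

    def levels(self) -> List[str]:
        return sorted({z.zone_level for z in self.zones}, key=ZONE_LEVELS.index)


@dataclass
class RwiPoints:
    """Sparse point estimates of the relative wealth index (unitless)."""

    x: np.ndarray
    y: np.ndarray
    rwi: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.rwi = np.asarray(self.rwi, float)
        if not (len(self.x) == len(self.y) == len(self.rwi)):
            raise ValueError("x, y, rwi must have equal length")
        if len(self.x) < 5:
            raise ValueError("need at least 5 RWI points to assign quintiles")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class Trajectory:
    """A timestamped GPS trace of one trip; t in seconds since trip start."""

    trip_id: int
    x: np.ndarray
    y: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.t = np.asarray(self.t, float)
        if len(self.x) < 2:
            raise ValueError("a trajectory needs at least two points")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("trajectory timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.x)
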