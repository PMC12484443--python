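"""File I/O: text rasters (Esri ASCII grid), GeoJSON vectors, CSV tables.

Rasters are exchanged as single-band Esri ASCII grids (.asc) — a plain-text
format carrying the full grid geometry (ncols/nrows/xllcorner/yllcorner/
cellsize) and a tagged NODATA value; values are written with enough digits
to round-trip float32 exactly.  Vectors (roads, zones, facilities, RWI
points) are GeoJSON; trajectories and tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .grid import GridSpec, Raster
from .vectors import (
    FacilityRegistry,
    RoadNetwork,
    RoadSegment,
    RwiPoints,
    Trajectory,
    Zone,
    ZonePolygons,
)

__all__ = [
    "write_raster",
    "read_raster",
    "write_roads",
    "read_roads",
    "write_facilities",
    "read_facilities",
    "write_zones",
    "read_zones",
    "write_rwi",
    "read_rwi",
    "write_trajectories",
    "read_trajectories",
]

_INF_SENTINEL = -8888.0  # encodes "unreachable" (+inf) distinctly from nodata


def write_raster(raster: Raster, path) -> None:
    """Write a raster as an Esri ASCII grid (.asc) with a JSON meta sidecar
    when the raster carries metadata."""
    spec = raster.grid
    data = np.asarray(raster.data, dtype=np.float64).copy()
    if np.issubdtype(np.asarray(raster.data).dtype, np.floating):
        data[np.isnan(np.asarray(raster.data, float))] = spec.nodata
        data[np.isposinf(np.asarray(raster.data, float))] = _INF_SENTINEL
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x!r}\n"
        f"yllcorner {spec.origin_y!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {spec.nodata!r}\n"
    )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.9g")
    if raster.meta:
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(raster.meta, fh, indent=1)


def read_raster(path, dtype=np.float32) -> Raster:
    """Read an Esri ASCII grid; NODATA becomes NaN, the unreachable sentinel
    becomes +inf (float rasters only)."""
    path = Path(path)
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    spec = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        nodata=header["nodata_value"],
    )
    if np.issubdtype(np.dtype(dtype), np.floating):
        data[data == spec.nodata] = np.nan
        data[data == _INF_SENTINEL] = np.inf
    data = data.astype(dtype)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Raster(spec, data, meta)


# ---------------------------------------------------------------------------
# GeoJSON vectors
# ---------------------------------------------------------------------------

def _write_geojson(features: List[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def _read_geojson(path) -> List[dict]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return doc["features"]


def write_roads(roads: RoadNetwork, path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(s.geometry),
            "properties": {"segment_id": s.segment_id, "road_class": s.road_class},
        }
        for s in roads.segments
    ]
    _write_geojson(feats, path)


def read_roads(path) -> RoadNetwork:
    segs = []
    for f in _read_geojson(path):
        geom = shape(f["geometry"])
        segs.append(
            RoadSegment(
                segment_id=int(f["properties"]["segment_id"]),
                road_class=f["properties"]["road_class"],
                coords=tuple(geom.coords),
            )
        )
    return RoadNetwork(segs)


def write_facilities(registry: FacilityRegistry, path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row.x, row.y]},
            "properties": {
                "facility_id": row.facility_id,
                "level": row.level,
                "sector": row.sector,
            },
        }
        for row in registry.table.itertuples()
    ]
    _write_geojson(feats, path)


def read_facilities(path) -> FacilityRegistry:
    rows = []
    for f in _read_geojson(path):
        x, y = f["geometry"]["coordinates"]
        rows.append(dict(x=x, y=y, **f["properties"]))
    return FacilityRegistry(pd.DataFrame(rows))


def write_zones(zones: ZonePolygons, path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(z.polygon),
            "properties": {"zone_id": z.zone_id, "zone_level": z.zone_level},
        }
        for z in zones.zones
    ]
    _write_geojson(feats, path)


def read_zones(path) -> ZonePolygons:
    zs = [
        Zone(
            zone_id=f["properties"]["zone_id"],
            zone_level=f["properties"]["zone_level"],
            polygon=shape(f["geometry"]),
        )
        for f in _read_geojson(path)
    ]
    return ZonePolygons(zs)


def write_rwi(rwi: RwiPoints, path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {"rwi": float(v)},
        }
        for x, y, v in zip(rwi.x, rwi.y, rwi.rwi)
    ]
    _write_geojson(feats, path)


def read_rwi(path) -> RwiPoints:
    feats = _read_geojson(path)
    xs = [f["geometry"]["coordinates"][0] for f in feats]
    ys = [f["geometry"]["coordinates"][1] for f in feats]
    vs = [f["properties"]["rwi"] for f in feats]
    return RwiPoints(np.array(xs), np.array(ys), np.array(vs))


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectories(trips: Sequence[Trajectory], path) -> None:
    frames = [
        pd.DataFrame({"trip_id": t.trip_id, "x": t.x, "y": t.y, "t": t.t})
        for t in trips
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path) -> List[Trajectory]:
    df = pd.read_csv(path)
    return [
        Trajectory(
            trip_id=int(tid),
            x=g["x"].to_numpy(),
            y=g["y"].to_numpy(),
            t=g["t"].to_numpy(),
        )
        for tid, g in df.groupby("trip_id", sort=True)
    ]
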