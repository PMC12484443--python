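"""Synthetic study areas with known ground truth.

Generates internally consistent landscapes — DEM, land cover, classed road
network, administrative zones, facility registry, WoCBA population, RWI
sample points, urbanicity bands and GPS trajectories — so every downstream
stage (speed estimation, friction, travel time, coverage, equity) is
testable without external data.  All generators are pure functions of their
inputs and an explicit integer seed.

The emulated structure mirrors a dense sub-Saharan metropolitan study area:
a 30 m planar grid, seven land-cover classes with open water as a barrier,
an eight-class road hierarchy, facilities stratified by level (hospital,
health center, medical center, clinic) and sector (government, faith-based,
private), a clustered population of women of childbearing age (WoCBA), a
spatial wealth gradient sampled at sparse points, and an ordinal urbanicity
continuum derived from population density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, box

from .classes import LANDCOVER_CLASSES, LANDCOVER_CODES, ROAD_CLASSES
from .grid import GridSpec, Raster
from .speeds import MS_TO_KMH, SpeedTable
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
    "LandscapeConfig",
    "gen_landscape",
    "gen_facilities",
    "gen_population_rwi_urbanicity",
    "gen_trajectories",
    "DEFAULT_FACILITY_COUNTS",
    "URBANICITY_BANDS",
]

#: default facility counts per level as (public, private) pairs — the
#: registry structure of a metropolitan area with 292 childbirth-care
#: facilities, 29% of them public
DEFAULT_FACILITY_COUNTS: Dict[str, Tuple[int, int]] = {
    "hospital": (10, 3),
    "health_center": (69, 6),
    "medical_center": (3, 45),
    "clinic": (2, 154),
}

#: ordinal settlement bands, least to most urban (code 0 .. 6)
URBANICITY_BANDS = (
    "very_low_density",
    "low_density",
    "village",
    "suburb",
    "town",
    "dense_town",
    "city",
)


@dataclass
class LandscapeConfig:
    """Tunable structure of the synthetic study area.

    Land-cover fractions must sum to 1; road counts are per class; zone
    counts control the nested administrative partition (departements split
    into communes split into arrondissements, and an independent health-zone
    partition).
    """

    landcover_fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "water": 0.08,
            "trees": 0.12,
            "flooded_vegetation": 0.05,
            "crops": 0.20,
            "built_area": 0.30,
            "rangeland": 0.15,
            "bare_ground": 0.10,
        }
    )
    landcover_smoothness: float = 4.0  # cells
    # DEM: sum of Gaussian bumps over a flat base (closed-form slopes)
    dem_base: float = 10.0
    dem_n_bumps: int = 6
    dem_amplitude: Tuple[float, float] = (5.0, 40.0)   # m
    dem_sigma_frac: Tuple[float, float] = (0.08, 0.25)  # fraction of extent
    road_counts: Dict[str, int] = field(
        default_factory=lambda: {
            "trunk": 2,
            "primary": 4,
            "secondary": 4,
            "tertiary": 6,
            "residential": 12,
            "service": 4,
            "unclassified": 3,
            "others": 0,
        }
    )
    road_vertices: Tuple[int, int] = (3, 5)
    n_departements: int = 3
    communes_per_departement: Tuple[int, ...] = (2, 1, 2)
    arrondissements_per_commune: int = 4
    n_health_zones: int = 7
    # population / wealth / urbanicity
    total_wocba: float = 10000.0
    n_pop_centres: int = 3
    pop_sigma_frac: float = 0.12        # cluster spread, fraction of extent
    pop_floor: float = 0.02             # uniform background share of density
    rwi_spacing: float = 300.0          # metres between RWI sample points
    rwi_gradient: float = 1.0           # total west-east wealth rise
    rwi_gradient_axis: str = "x"        # "x" (west-east) or "y" (south-north)
    rwi_noise_sd: float = 0.1
    urbanicity_quantiles: Tuple[float, ...] = (0.30, 0.50, 0.65, 0.80, 0.90, 0.97)
    urbanicity_smoothness: float = 3.0  # cells

    def validate(self) -> None:
        total = sum(self.landcover_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"land-cover fractions sum to {total}, not 1")
        unknown = set(self.landcover_fractions) - set(LANDCOVER_CLASSES)
        if unknown:
            raise ValueError(f"unknown land-cover classes {sorted(unknown)}")
        if any(v < 0 for v in self.landcover_fractions.values()):
            raise ValueError("land-cover fractions must be nonnegative")
        unknown_r = set(self.road_counts) - set(ROAD_CLASSES)
        if unknown_r:
            raise ValueError(f"unknown road classes {sorted(unknown_r)}")
        if self.total_wocba <= 0:
            raise ValueError("total_wocba must be positive")
        if not all(0 < q < 1 for q in self.urbanicity_quantiles) or (
            sorted(self.urbanicity_quantiles) != list(self.urbanicity_quantiles)
        ):
            raise ValueError("urbanicity quantiles must be sorted in (0, 1)")


# ---------------------------------------------------------------------------
# terrain, land cover, roads, zones
# ---------------------------------------------------------------------------

def _gen_dem(spec: GridSpec, config: LandscapeConfig, rng: np.random.Generator) -> Raster:
    X, Y = spec.center_mesh()
    elev = np.full(spec.shape, config.dem_base, float)
    ext = max(spec.width, spec.height)
    for _ in range(config.dem_n_bumps):
        cx = spec.origin_x + rng.uniform(0, spec.width)
        cy = spec.origin_y + rng.uniform(0, spec.height)
        amp = rng.uniform(*config.dem_amplitude)
        sig = rng.uniform(*config.dem_sigma_frac) * ext
        elev += amp * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sig**2))
    return Raster(spec, elev)


def _gen_landcover(
    spec: GridSpec, config: LandscapeConfig, rng: np.random.Generator
) -> Raster:
    """Threshold a smooth random field at rank cutoffs, so class shares hit
    the configured fractions exactly up to one cell of rounding."""
    fld = gaussian_filter(
        rng.standard_normal(spec.shape), sigma=config.landcover_smoothness
    )
    n = fld.size
    order = np.argsort(fld.ravel(), kind="stable")
    out = np.full(n, LANDCOVER_CODES["bare_ground"], dtype=np.int16)
    # wetter classes occupy the low end of the field (depressions)
    fill_order = [
        "water", "flooded_vegetation", "trees", "crops",
        "rangeland", "bare_ground", "built_area",
    ]
    start = 0
    for name in fill_order:
        frac = config.landcover_fractions.get(name, 0.0)
        count = int(round(frac * n))
        out[order[start : start + count]] = LANDCOVER_CODES[name]
        start += count
    if start < n:  # rounding remainder goes to the last non-empty class
        out[order[start:]] = out[order[start - 1]] if start else LANDCOVER_CODES["bare_ground"]
    return Raster(spec, out.reshape(spec.shape))


def _random_polyline(
    rng: np.random.Generator,
    start: Tuple[float, float],
    spec: GridSpec,
    n_extra: int,
    step: float,
) -> List[Tuple[float, float]]:
    xmin, ymin, xmax, ymax = spec.extent
    eps = spec.cell_size * 0.05
    lo_x, hi_x = xmin + eps, xmax - eps
    lo_y, hi_y = ymin + eps, ymax - eps
    pts = [start]
    heading = rng.uniform(0, 2 * np.pi)
    for _ in range(n_extra):
        heading += rng.normal(0, 0.6)
        x = pts[-1][0] + step * np.cos(heading)
        y = pts[-1][1] + step * np.sin(heading)
        # mirror-reflect off the extent so polylines stay strictly inside
        # without collapsing onto (and overlapping along) the boundary
        if x < lo_x or x > hi_x:
            x = float(np.clip(2 * (lo_x if x < lo_x else hi_x) - x, lo_x, hi_x))
            heading = np.pi - heading
        if y < lo_y or y > hi_y:
            y = float(np.clip(2 * (lo_y if y < lo_y else hi_y) - y, lo_y, hi_y))
            heading = -heading
        if abs(x - pts[-1][0]) < eps and abs(y - pts[-1][1]) < eps:
            continue
        pts.append((x, y))
    return pts


def _gen_roads(
    spec: GridSpec, config: LandscapeConfig, rng: np.random.Generator
) -> RoadNetwork:
    """Connected classed polylines: a trunk backbone spans the extent and
    every further segment starts on an existing one."""
    xmin, ymin, xmax, ymax = spec.extent
    eps = spec.cell_size * 0.05
    segments: List[RoadSegment] = []
    geoms: List[LineString] = []
    sid = 0
    step = max(spec.width, spec.height) / 4.0
    for cls in ROAD_CLASSES:
        for k in range(config.road_counts.get(cls, 0)):
            if not segments:
                # backbone spanning the extent west to east
                ys = rng.uniform(ymin + eps, ymax - eps, size=3)
                pts = [
                    (xmin + eps, float(ys[0])),
                    ((xmin + xmax) / 2, float(ys[1])),
                    (xmax - eps, float(ys[2])),
                ]
            else:
                host = geoms[rng.integers(0, len(geoms))]
                origin = host.interpolate(rng.uniform(0, host.length))
                n_extra = int(rng.integers(*config.road_vertices))
                pts = _random_polyline(
                    rng, (origin.x, origin.y), spec, n_extra, step
                )
                if len(pts) < 2:
                    pts.append((pts[0][0] + eps * 2, pts[0][1] + eps * 2))
            seg = RoadSegment(segment_id=sid, road_class=cls, coords=tuple(pts))
            segments.append(seg)
            geoms.append(seg.geometry)
            sid += 1
    return RoadNetwork(segments)


def _split_positions(lo: float, hi: float, n: int, cell: float) -> List[float]:
    """n+1 cut positions aligned to cell edges, so no cell centre sits on a
    zone boundary."""
    total_cells = int(round((hi - lo) / cell))
    cuts = [lo + cell * int(round(i * total_cells / n)) for i in range(n + 1)]
    if len(set(cuts)) != n + 1:
        raise ValueError(f"extent too small to split into {n} zones")
    return cuts


def _gen_zones(spec: GridSpec, config: LandscapeConfig) -> ZonePolygons:
    xmin, ymin, xmax, ymax = spec.extent
    cell = spec.cell_size
    zones: List[Zone] = [
        Zone("study_area", "study_area", box(xmin, ymin, xmax, ymax))
    ]
    if len(config.communes_per_departement) != config.n_departements:
        raise ValueError("communes_per_departement must list one count per departement")
    dep_cuts = _split_positions(xmin, xmax, config.n_departements, cell)
    commune_boxes = []
    for d in range(config.n_departements):
        dx0, dx1 = dep_cuts[d], dep_cuts[d + 1]
        zones.append(Zone(f"D{d + 1}", "departement", box(dx0, ymin, dx1, ymax)))
        n_com = config.communes_per_departement[d]
        com_cuts = _split_positions(ymin, ymax, n_com, cell)
        for c in range(n_com):
            cy0, cy1 = com_cuts[c], com_cuts[c + 1]
            cid = f"D{d + 1}-C{c + 1}"
            zones.append(Zone(cid, "commune", box(dx0, cy0, dx1, cy1)))
            commune_boxes.append((cid, dx0, cy0, dx1, cy1))
            arr_cuts = _split_positions(
                dx0, dx1, config.arrondissements_per_commune, cell
            )
            for a in range(config.arrondissements_per_commune):
                zones.append(
                    Zone(
                        f"{cid}-A{a + 1}",
                        "arrondissement",
                        box(arr_cuts[a], cy0, arr_cuts[a + 1], cy1),
                    )
                )
    hz_cuts = _split_positions(xmin, xmax, config.n_health_zones, cell)
    for h in range(config.n_health_zones):
        zones.append(
            Zone(f"HZ{h + 1}", "health_zone", box(hz_cuts[h], ymin, hz_cuts[h + 1], ymax))
        )
    return ZonePolygons(zones)


def gen_landscape(
    spec: GridSpec, config: Optional[LandscapeConfig] = None, seed: int = None
) -> Tuple[Raster, Raster, RoadNetwork, ZonePolygons]:
    """Generate (DEM, land cover, road network, zones) for one study area.

    Deterministic for fixed (spec, config, seed); the seed is mandatory.
    """
    if seed is None:
        raise ValueError("a seed is required: synthetic data must be reproducible")
    config = config or LandscapeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    dem = _gen_dem(spec, config, rng)
    landcover = _gen_landcover(spec, config, rng)
    roads = _gen_roads(spec, config, rng)
    zones = _gen_zones(spec, config)
    return dem, landcover, roads, zones


# ---------------------------------------------------------------------------
# facilities
# ---------------------------------------------------------------------------

def gen_facilities(
    spec: GridSpec,
    counts: Optional[Dict[str, Tuple[int, int]]] = None,
    clustering: float = 1.0,
    seed: int = None,
    pop: Optional[Raster] = None,
    roads: Optional[RoadNetwork] = None,
    fbo_share: float = 5.0 / 29.0,
) -> FacilityRegistry:
    """Facility registry with exact per-(level, sector-group) counts.

    ``counts`` maps level -> (public, private); public facilities split
    between government and faith-based sectors by ``fbo_share`` (default
    keeps the 24%/5% government/FBO split of the default registry).  With a
    population raster, placement probability scales with density to the
    ``clustering`` power; with a road network, each facility snaps to the
    nearest point on a road so it always sits on a passable cell.
    """
    if seed is None:
        raise ValueError("a seed is required: synthetic data must be reproducible")
    counts = counts or DEFAULT_FACILITY_COUNTS
    if any(p < 0 or q < 0 for p, q in counts.values()):
        raise ValueError("facility counts must be nonnegative")
    total = sum(p + q for p, q in counts.values())
    if total == 0:
        raise ValueError("at least one facility is required (Dijkstra needs a source)")
    rng = np.random.default_rng(seed)

    def draw_xy(n: int) -> np.ndarray:
        if n == 0:
            return np.empty((0, 2))
        if pop is not None:
            dens = np.clip(np.asarray(pop.data, float), 0, None) + 1e-12
            p = dens.ravel() ** clustering
            p /= p.sum()
            flat = rng.choice(dens.size, size=n, p=p)
            r, c = np.unravel_index(flat, pop.grid.shape)
            x, y = pop.grid.cell_center(r, c)
            jit = rng.uniform(-0.45, 0.45, size=(n, 2)) * spec.cell_size
            return np.column_stack([x, y]) + jit
        xmin, ymin, xmax, ymax = spec.extent
        return np.column_stack(
            [rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)]
        )

    rows = []
    fid = 0
    for level in counts:
        n_public, n_private = counts[level]
        n_fbo = int(round(n_public * fbo_share))
        sectors = (
            ["public_government"] * (n_public - n_fbo)
            + ["public_fbo"] * n_fbo
            + ["private"] * n_private
        )
        xy = draw_xy(len(sectors))
        for (x, y), sector in zip(xy, sectors):
            rows.append(dict(facility_id=f"F{fid:04d}", x=x, y=y,
                             level=level, sector=sector))
            fid += 1

    if roads is not None and len(roads) and rows:
        import shapely
        from shapely.strtree import STRtree

        geoms = roads.geometries()
        tree = STRtree(geoms)
        xmin, ymin, xmax, ymax = spec.extent
        eps = spec.cell_size * 0.01
        for r in rows:
            pt = shapely.points(r["x"], r["y"])
            near = geoms[int(tree.nearest(pt))]
            snapped = near.interpolate(near.project(pt))
            r["x"] = float(np.clip(snapped.x, xmin + eps, xmax - eps))
            r["y"] = float(np.clip(snapped.y, ymin + eps, ymax - eps))

    import pandas as pd

    return FacilityRegistry(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# population, wealth, urbanicity
# ---------------------------------------------------------------------------

def gen_population_rwi_urbanicity(
    spec: GridSpec, config: Optional[LandscapeConfig] = None, seed: int = None
) -> Tuple[Raster, RwiPoints, Raster]:
    """Clustered WoCBA counts, sparse RWI points with a spatial wealth
    gradient, and urbanicity bands from thresholded smoothed density.

    The raster total equals ``config.total_wocba`` exactly (normalised); the
    RWI ground truth is the configured gradient (noise sd 0 makes the
    gradient exact).  Urbanicity band k+1 cells all have smoothed density at
    least as high as any band-k cell, by construction.
    """
    if seed is None:
        raise ValueError("a seed is required: synthetic data must be reproducible")
    config = config or LandscapeConfig()
    config.validate()
    if config.rwi_spacing <= spec.cell_size:
        raise ValueError("rwi_spacing must exceed the cell size")
    rng = np.random.default_rng(seed)
    X, Y = spec.center_mesh()
    ext = max(spec.width, spec.height)

    dens = np.full(spec.shape, config.pop_floor, float)
    for _ in range(config.n_pop_centres):
        cx = spec.origin_x + rng.uniform(0.2, 0.8) * spec.width
        cy = spec.origin_y + rng.uniform(0.2, 0.8) * spec.height
        sig = config.pop_sigma_frac * ext
        dens += rng.uniform(0.5, 1.5) * np.exp(
            -((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sig**2)
        )
    wocba = dens / dens.sum() * config.total_wocba
    pop = Raster(spec, wocba)

    xmin, ymin, xmax, ymax = spec.extent
    s = config.rwi_spacing
    gx = np.arange(xmin + s / 2, xmax, s)
    gy = np.arange(ymin + s / 2, ymax, s)
    if gx.size * gy.size < 5:
        raise ValueError(
            "rwi_spacing too large: fewer than 5 RWI points fit in the extent"
        )
    PX, PY = np.meshgrid(gx, gy)
    px = PX.ravel() + rng.uniform(-0.25, 0.25, PX.size) * s
    py = PY.ravel() + rng.uniform(-0.25, 0.25, PY.size) * s
    px = np.clip(px, xmin, np.nextafter(xmax, -np.inf))
    py = np.clip(py, ymin, np.nextafter(ymax, -np.inf))
    along = (px - xmin) / spec.width if config.rwi_gradient_axis == "x" else (
        (py - ymin) / spec.height
    )
    rwi_vals = config.rwi_gradient * (along - 0.5) + rng.normal(
        0, config.rwi_noise_sd, px.size
    )
    rwi = RwiPoints(px, py, rwi_vals)

    smoothed = gaussian_filter(wocba, sigma=config.urbanicity_smoothness)
    cuts = np.quantile(smoothed, config.urbanicity_quantiles)
    bands = np.searchsorted(cuts, smoothed, side="right").astype(np.int16)
    urb = Raster(spec, bands, meta={"band_names": list(URBANICITY_BANDS)})
    return pop, rwi, urb


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def gen_trajectories(
    roads: RoadNetwork,
    truth: SpeedTable,
    n_trips: int,
    gps_noise_sd: float = 0.0,
    sampling_dt: float = 1.0,
    seed: int = None,
    speed_jitter_sd: float = 0.0,
) -> List[Trajectory]:
    """GPS trips along road segments at known per-class ground-truth speeds.

    Trips cycle over segments (sorted by id) so every class in the network
    is covered when ``n_trips >= len(roads)``.  Each trip traverses one full
    segment at the class's mean-scenario truth speed, optionally perturbed
    per trip by ``speed_jitter_sd`` (km/h, truncated positive); points are
    sampled every ``sampling_dt`` seconds plus the exact moments the trip
    passes a polyline vertex (so consecutive points always lie on a straight
    piece and chord distance equals distance travelled, making ground-truth
    speeds exactly recoverable), then perturbed per coordinate by
    N(0, gps_noise_sd) metres.
    """
    if seed is None:
        raise ValueError("a seed is required: synthetic data must be reproducible")
    if sampling_dt <= 0:
        raise ValueError("sampling_dt must be positive")
    if n_trips < 1:
        raise ValueError("n_trips must be at least 1")
    if len(roads) == 0:
        raise ValueError("road network is empty")
    for cls in sorted(roads.classes_present()):
        if not truth.has("road", cls):
            raise ValueError(f"truth speed table does not cover road class {cls!r}")
    rng = np.random.default_rng(seed)
    segs = sorted(roads.segments, key=lambda s: s.segment_id)
    trips: List[Trajectory] = []
    for trip_id in range(n_trips):
        seg = segs[trip_id % len(segs)]
        v_kmh = truth.speed_kmh("road", seg.road_class, "average")
        if speed_jitter_sd > 0:
            v_kmh = max(0.1, v_kmh + rng.normal(0, speed_jitter_sd))
        geom = seg.geometry
        v_ms = v_kmh / MS_TO_KMH
        duration = geom.length * MS_TO_KMH / v_kmh  # seconds
        ticks = np.arange(0.0, duration + 1e-9, sampling_dt)
        pts_xy = np.asarray(seg.coords, float)
        arc = np.concatenate(
            [[0.0], np.cumsum(np.hypot(*np.diff(pts_xy, axis=0).T))]
        )
        vertex_times = arc / v_ms
        ts = np.unique(np.concatenate([ticks, vertex_times, [duration]]))
        ts = ts[np.concatenate([[True], np.diff(ts) > 1e-9])]
        if len(ts) < 2:
            ts = np.array([0.0, max(duration, 1e-6)])
        dist = ts * (v_kmh / MS_TO_KMH)
        pts = [geom.interpolate(d) for d in dist]
        x = np.array([p.x for p in pts])
        y = np.array([p.y for p in pts])
        if gps_noise_sd > 0:
            x = x + rng.normal(0, gps_noise_sd, x.size)
            y = y + rng.normal(0, gps_noise_sd, y.size)
        trips.append(Trajectory(trip_id=trip_id, x=x, y=y, t=ts))
    return trips
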