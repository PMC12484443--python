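"""Per-road-class travel-speed estimation from timestamped GPS trajectories.

Trips recorded on tablets or smartphones are map-matched to the nearest road
segment within a buffer, consecutive matched points give distance/time speed
observations, and observations are aggregated into a per-class speed table
(mean, min, max, sample sd) that drives the three travel scenarios
(minimum / average / maximum speed).

Land-cover (off-road walking) speeds are not estimated from traces; they are
fixed reference values, with open water a hard barrier (0 km/h).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from shapely.strtree import STRtree

from .classes import LANDCOVER_CLASSES, ROAD_CLASSES, SCENARIO_COLUMN
from .vectors import RoadNetwork, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "SpeedObservation",
    "SpeedTable",
    "DEFAULT_ROAD_SPEEDS",
    "DEFAULT_LANDCOVER_SPEEDS",
    "OTHERS_FIXED_SPEEDS",
    "default_speed_table",
    "match_to_road",
    "point_pair_speeds",
    "aggregate_speed_table",
]

MS_TO_KMH = 3.6

#: Default motorized speeds (km/h) by road class: mean, min, max, sd.
#: Field-measured values for a congested West African metropolitan network;
#: used by the synthetic generator as ground truth and as the fallback table.
DEFAULT_ROAD_SPEEDS: Dict[str, Tuple[float, float, float, float]] = {
    "trunk": (20.4, 6.2, 38.0, 8.9),
    "primary": (18.0, 3.1, 38.0, 9.0),
    "secondary": (15.1, 4.4, 30.0, 5.8),
    "tertiary": (15.3, 4.1, 33.3, 8.5),
    "residential": (12.6, 0.84, 38.0, 7.0),
    "service": (9.6, 4.2, 25.5, 4.1),
    "unclassified": (17.1, 6.2, 32.0, 7.8),
    "others": (5.0, 4.0, 6.0, np.nan),
}

#: "Others" roads (footways, cycleways, steps) are walked, not driven; their
#: speeds are fixed, never estimated from motorized traces.
OTHERS_FIXED_SPEEDS: Tuple[float, float, float] = (5.0, 4.0, 6.0)

#: Default walking speeds (km/h) by land cover: mean, min, max.  Water is an
#: absolute barrier.
DEFAULT_LANDCOVER_SPEEDS: Dict[str, Tuple[float, float, float]] = {
    "water": (0.0, 0.0, 0.0),
    "trees": (2.5, 2.0, 3.0),
    "flooded_vegetation": (0.1, 0.08, 0.12),
    "crops": (4.0, 3.6, 4.8),
    "built_area": (5.0, 4.0, 6.0),
    "rangeland": (4.5, 4.05, 5.4),
    "bare_ground": (5.0, 4.0, 6.0),
}


@dataclass(frozen=True)
class SpeedObservation:
    """One distance/time speed estimate between consecutive matched points."""

    trip_id: int
    segment_id: int
    road_class: str
    speed_kmh: float
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.speed_kmh) or self.speed_kmh < 0:
            raise ValueError("speed must be finite and nonnegative")


class SpeedTable:
    """Per-class speed summaries driving the scenario engine.

    Backed by a DataFrame with columns
    ``class_kind`` ('road' | 'landcover'), ``class``, ``mean``, ``min``,
    ``max``, ``sd``, ``n`` — speeds in km/h.
    """

    COLUMNS = ("class_kind", "class", "mean", "min", "max", "sd", "n")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"speed table missing columns {missing}")
        self.table = table.reset_index(drop=True)
        self._validate()
        self._index = {
            (k, c): i
            for i, (k, c) in enumerate(zip(table["class_kind"], table["class"]))
        }

    def _validate(self) -> None:
        t = self.table
        # tolerance: the float mean of identical values can sit an ulp
        # outside [min, max]
        eps = 1e-9 * np.maximum(1.0, t["max"].abs())
        bad = t[(t["min"] > t["mean"] + eps) | (t["mean"] > t["max"] + eps)]
        if len(bad):
            raise ValueError(
                f"min <= mean <= max violated for {bad['class'].tolist()}"
            )
        if (t["sd"].dropna() < 0).any():
            raise ValueError("sd must be nonnegative")
        water = t[(t["class_kind"] == "landcover") & (t["class"] == "water")]
        if len(water) and water[["mean", "min", "max"]].to_numpy().any():
            raise ValueError("water must be a barrier (0 km/h in every column)")

    def speed_kmh(self, class_kind: str, cls: str, scenario: str) -> float:
        """Speed (km/h) of a class under a scenario (minimum/average/maximum)."""
        col = SCENARIO_COLUMN[scenario]
        try:
            i = self._index[(class_kind, cls)]
        except KeyError:
            raise KeyError(f"class {cls!r} ({class_kind}) not in speed table") from None
        return float(self.table.at[i, col])

    def has(self, class_kind: str, cls: str) -> bool:
        return (class_kind, cls) in self._index

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpeedTable":
        return cls(pd.read_csv(path))


def default_speed_table() -> SpeedTable:
    """The bundled reference speed table (road + land-cover rows)."""
    rows = []
    for name in ROAD_CLASSES:
        mean, lo, hi, sd = DEFAULT_ROAD_SPEEDS[name]
        rows.append(("road", name, mean, lo, hi, sd, np.nan))
    for name in LANDCOVER_CLASSES:
        mean, lo, hi = DEFAULT_LANDCOVER_SPEEDS[name]
        rows.append(("landcover", name, mean, lo, hi, np.nan, np.nan))
    return SpeedTable(pd.DataFrame(rows, columns=SpeedTable.COLUMNS))


# ---------------------------------------------------------------------------
# map matching
# ---------------------------------------------------------------------------

def match_to_road(
    traj: Trajectory, roads: RoadNetwork, buffer: float = 20.0
) -> List[Optional[Tuple[int, str]]]:
    """Match each trajectory point to the nearest road segment within buffer.

    Returns one entry per point: ``(segment_id, road_class)`` or ``None`` if
    no segment lies within ``buffer`` metres.  Distance ties (within 1e-9 m)
    are broken toward the smallest segment_id.
    """
    if buffer <= 0:
        raise ValueError("buffer must be positive")
    if len(roads) == 0:
        raise ValueError("cannot match against an empty road network")

    segs = sorted(roads.segments, key=lambda s: s.segment_id)
    geoms = np.array([s.geometry for s in segs], dtype=object)
    tree = STRtree(list(geoms))

    out: List[Optional[Tuple[int, str]]] = []
    pts = shapely.points(traj.x, traj.y)
    # query all points at once against buffered envelopes
    cand_pt, cand_seg = tree.query(shapely.buffer(pts, buffer))
    by_point: Dict[int, List[int]] = {}
    for pi, si in zip(cand_pt, cand_seg):
        by_point.setdefault(int(pi), []).append(int(si))
    for i in range(len(traj)):
        cand = by_point.get(i)
        if not cand:
            out.append(None)
            continue
        d = shapely.distance(geoms[cand], pts[i])
        dmin = d.min()
        if dmin > buffer:
            out.append(None)
            continue
        # segs sorted by id, so first index at the minimal distance wins ties
        best = min(j for j, dj in zip(cand, d) if dj <= dmin + 1e-9)
        out.append((segs[best].segment_id, segs[best].road_class))
    return out


def point_pair_speeds(
    traj: Trajectory,
    matches: Sequence[Optional[Tuple[int, str]]],
    max_gap: float = 30.0,
) -> List[SpeedObservation]:
    """Euclidean-distance / elapsed-time speeds for consecutive matched points.

    A pair contributes only when both points matched the same segment or the
    same road class, and the time gap is positive and at most ``max_gap``
    seconds.  Zero time gaps are skipped with a warning rather than raised.
    """
    if len(matches) != len(traj):
        raise ValueError("one match entry required per trajectory point")
    obs: List[SpeedObservation] = []
    for i in range(len(traj) - 1):
        ma, mb = matches[i], matches[i + 1]
        if ma is None or mb is None:
            continue
        if ma[0] != mb[0] and ma[1] != mb[1]:
            continue
        dt = traj.t[i + 1] - traj.t[i]
        if dt == 0:
            logger.warning(
                "trip %s: zero time gap at point %d; pair skipped", traj.trip_id, i
            )
            continue
        if dt > max_gap:
            continue
        dist = float(np.hypot(traj.x[i + 1] - traj.x[i], traj.y[i + 1] - traj.y[i]))
        obs.append(
            SpeedObservation(
                trip_id=traj.trip_id,
                segment_id=ma[0],
                road_class=ma[1],
                speed_kmh=dist / dt * MS_TO_KMH,
                t_start=float(traj.t[i]),
                t_end=float(traj.t[i + 1]),
            )
        )
    return obs


def aggregate_speed_table(
    obs: Sequence[SpeedObservation],
    landcover_speeds: Optional[Dict[str, Tuple[float, float, float]]] = None,
    outlier_cap: float = 120.0,
    required_classes: Optional[Sequence[str]] = None,
    fallback: Optional[Dict[str, str]] = None,
    qc: Optional[dict] = None,
) -> SpeedTable:
    """Aggregate observations into a per-class speed table.

    Parameters
    ----------
    obs:
        Speed observations from :func:`point_pair_speeds`.
    landcover_speeds:
        Fixed land-cover walking speeds (mean, min, max) in km/h; defaults to
        the bundled reference values.
    outlier_cap:
        Observations above this speed (km/h) are treated as GPS glitches,
        dropped, and counted in the QC report.
    required_classes:
        Road classes that must be covered; defaults to the classes observed.
        "others" is always filled from its fixed walking speeds.
    fallback:
        Optional map from an unobserved class to the class whose estimates it
        borrows.
    qc:
        Optional dict collecting quality-control counters
        (``dropped_outliers``, ``fallback_classes``).

    sd uses the n-1 (sample) denominator; classes with a single observation
    report sd 0.
    """
    if landcover_speeds is None:
        landcover_speeds = DEFAULT_LANDCOVER_SPEEDS
    fallback = fallback or {}
    if qc is None:
        qc = {}

    kept = [o for o in obs if o.speed_kmh <= outlier_cap]
    qc["dropped_outliers"] = len(obs) - len(kept)
    qc["fallback_classes"] = {}

    by_class: Dict[str, List[float]] = {}
    for o in kept:
        by_class.setdefault(o.road_class, []).append(o.speed_kmh)

    if required_classes is None:
        required_classes = [c for c in ROAD_CLASSES if c in by_class or c == "others"]

    rows = []
    for name in ROAD_CLASSES:
        if name not in required_classes and name not in by_class:
            continue
        if name == "others":
            mean, lo, hi = OTHERS_FIXED_SPEEDS
            rows.append(("road", name, mean, lo, hi, np.nan, np.nan))
            continue
        vals = by_class.get(name)
        if vals is None and name in fallback:
            src = fallback[name]
            vals = by_class.get(src)
            qc["fallback_classes"][name] = src
        if not vals:
            raise ValueError(
                f"road class {name!r} has no speed observations and no fallback"
            )
        a = np.asarray(vals, float)
        sd = float(a.std(ddof=1)) if len(a) > 1 else 0.0
        rows.append(
            ("road", name, float(a.mean()), float(a.min()), float(a.max()), sd, len(a))
        )
    for name in LANDCOVER_CLASSES:
        mean, lo, hi = landcover_speeds[name]
        rows.append(("landcover", name, mean, lo, hi, np.nan, np.nan))
    return SpeedTable(pd.DataFrame(rows, columns=SpeedTable.COLUMNS))
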