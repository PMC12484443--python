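"""Closed class sets: road types, land use/cover codes, facility strata.

The road taxonomy follows the OSM highway hierarchy collapsed to the eight
classes used for speed estimation; "others" collects pedestrian-only ways
(footway, cycleway, steps, living street) which are traversed at walking
speeds.  Land cover uses a seven-class scheme in which open water is an
absolute barrier to movement.
"""

from __future__ import annotations

ROAD_CLASSES = (
    "trunk",
    "primary",
    "secondary",
    "tertiary",
    "residential",
    "service",
    "unclassified",
    "others",
)

#: road classes traversed on foot rather than by motor vehicle
WALKING_ROAD_CLASSES = frozenset({"others"})

LANDCOVER_CLASSES = (
    "water",
    "trees",
    "flooded_vegetation",
    "crops",
    "built_area",
    "rangeland",
    "bare_ground",
)

#: integer raster codes, 0-based in LANDCOVER_CLASSES order
LANDCOVER_CODES = {name: i for i, name in enumerate(LANDCOVER_CLASSES)}
LANDCOVER_NAMES = {i: name for name, i in LANDCOVER_CODES.items()}
WATER_CODE = LANDCOVER_CODES["water"]

FACILITY_LEVELS = ("hospital", "health_center", "medical_center", "clinic")
FACILITY_SECTORS = ("public_government", "public_fbo", "private")
PUBLIC_SECTORS = frozenset({"public_government", "public_fbo"})

#: the four analysis strata for facility selection
STRATA = ("all", "public", "hospitals", "public_hospitals")

SCENARIOS = ("minimum", "average", "maximum")
#: scenario name -> SpeedTable column
SCENARIO_COLUMN = {"minimum": "min", "average": "mean", "maximum": "max"}

ZONE_LEVELS = ("arrondissement", "commune", "health_zone", "departement", "study_area")
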