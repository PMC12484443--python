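# Methods

## Model

`accessim` treats geographic accessibility as a least-cost-path problem on a
regular raster grid in a planar metric CRS. Every layer — elevation, land
cover, traversal speed, travel time, population, urbanicity — shares one
grid geometry (`GridSpec`; default cell size 30 m, row 0 at the northern
edge, origin at the lower-left corner). Real-data use expects the caller to
supply layers already projected to an equal-area or UTM CRS; the package
does no geodesy, which keeps cell-distance arithmetic exact and testable.

### Friction surface

Traversal speed per cell is the merge of two regimes:

* **Road cells** carry the motorized speed of their road class under the
  chosen scenario. Rasterization is supercover: a cell is painted whenever
  a segment touches any part of it, so thin diagonal roads remain
  8-connected on the grid. Where classes conflict in one cell, the class
  with the higher mean speed wins. Pedestrian-only ("others") road cells
  are walked, not driven.
* **Off-road cells** carry the land-cover walking speed. Open water is an
  absolute barrier (0 km/h) in every scenario; bridges are not modelled, so
  a road crossing water is severed there.

Speeds come from a `SpeedTable` with one row per road class (mean, min,
max, sample sd, n) and per land-cover class (mean, min, max). The three
scenario names map onto columns: minimum → min, average → mean, maximum →
max, giving a worst-case / typical / best-case continuum from a single
estimation pass. The bundled default table reflects field-measured speeds
in a congested West African metropolitan network: trunk roads average
20.4 km/h and residential roads 12.6 km/h, with walking speeds of
2.5–5 km/h off-road and 0.1 km/h in flooded vegetation. Note one deliberate
asymmetry of the defaults: the residential minimum (0.84 km/h, a
traffic-jam crawl) is *below* every off-road walking minimum, so the
"roads are never slower than their surroundings" intuition holds for the
average and maximum columns only.

### Slope adjustment

Walking speeds are flat-ground speeds. At move time they are multiplied by
a normalized Tobler hiking factor

    f(s) = exp(−3.5·|s + 0.05|) / exp(−3.5·0.05)

for the signed slope `s = Δelev/d` of the move, so `f(0) = 1` exactly and
the factor peaks (≈1.19) on a gentle −5 % descent. The adjustment is
anisotropic — applied per directed move, not baked into the raster —
because a climb and its reverse descent cost differently. Motorized cells
ignore slope: vehicle speeds were observed on real terrain and already
embody it. Slopes with |s| ≥ 10 (rise/run) are rejected as data errors.

### Cost accumulation

The travel-time surface is a multi-source Dijkstra
(`scipy.sparse.csgraph.dijkstra`, min over all sources) on the directed
lattice graph. A move from cell *a* to neighbour *b* at centre distance *d*
(cell, cell·√2, or cell·√5 for the optional 16-neighbourhood knight moves)
costs

    d · (0.5 / v_a→b + 0.5 / v_b→a→b)

i.e. half the move is traversed at each cell's effective speed in the
direction of travel; a boundary move between regimes costs the mean of the
two. With this symmetric half-cell form the surface is identical whether
accumulated population→facility or facility→population (exactly true on
flat terrain; on slopes the directed graph is transposed so the
population→facility direction is the one computed). Cells with zero speed
are barriers; cells with no path through nonzero-speed cells are reported
as +inf (unreachable), never silently dropped.

Facilities map to their containing cell; a facility on a barrier cell snaps
to the nearest passable cell within 3 cells (ties broken by distance, then
row/column order) or is dropped with a logged warning. Connectivity
defaults to 8; 16 reduces octile anisotropy at ~2× edge count. Output is
minutes, kept at full precision internally and rounded only in reports.

### Speed survey

Each GPS point matches the nearest road segment within a buffer (default
20 m; ties to the smallest segment id). Consecutive points matched to the
same segment or same class yield one observation: Euclidean distance over
elapsed time, km/h. Pairs spanning unmatched points, zero time gaps
(warned, skipped) or gaps above 30 s are discarded; observations above a
120 km/h outlier cap are dropped and counted in the QC report. Class
summaries use the sample (n−1) sd. The "others" class is never estimated
from motorized traces; it keeps fixed walking-range speeds (5.0 / 4.0 /
6.0 km/h). An unobserved class may borrow another class's estimates through
an explicit fallback map; otherwise it is an error naming the class.
Full HMM (Viterbi) map matching is out of scope; the nearest-segment rule
is exact for the synthetic trajectories and adequate for dense urban
sampling intervals.

### Coverage and zonal statistics

Travel time is first constrained to populated cells (WoCBA > `min_pop`,
default 0). A cell belongs to the zone containing its centre (ties to the
lexicographically smallest zone id), making each zone level an exact
partition — so commune-level covered population sums exactly to the study
area, a property the tests assert. Zonal summaries report both the
unweighted mean over populated reachable cells and a population-weighted
mean, since either convention appears in practice. Coverage at threshold T
is `100 · Σ wocba[tt ≤ T] / Σ wocba` per zone; unreachable populated cells
stay in the denominator (coverage is a claim about all women), and a
zero-population zone reports NaN, never 0.

### Equity analysis

Each populated cell takes the RWI of the nearest sample point (Euclidean,
cell centres; ties to the lowest point index — no interpolation, matching
how sparse RWI estimates are published). Quintiles are
population-weighted: cells sorted by RWI, each assigned the quintile
containing the midpoint of its cumulative-weight span (boundary midpoints
round up), so every quintile holds 20 % of women within one cell's weight.
The equiplot statistic is the WoCBA-weighted mean travel time per quintile
(a weighted median column is also emitted); per-quintile means and weights
recombine exactly to the global weighted mean. The urbanicity summary is
the weighted mean travel time per ordinal settlement band.

## Synthetic landscapes

The generator emulates the structure of a dense coastal metropolitan study
area so that every downstream stage has known ground truth:

* **DEM** — sum of Gaussian bumps over a flat base (closed-form slopes, so
  slope-factor behaviour is verifiable analytically).
* **Land cover** — a Gaussian-smoothed random field thresholded at rank
  cutoffs; class shares hit the configured fractions to within one cell.
  Wet classes occupy the field's depressions, so water forms contiguous
  bodies.
* **Roads** — a trunk backbone spans the extent west–east; every later
  segment starts on an existing one (the network is connected by
  construction) and random-walks with mirror reflection off the extent —
  reflection rather than clamping, so polylines never collapse onto and
  overlap along the boundary. Default counts (2 trunk … 12 residential)
  keep the paper-style class mix at desk scale.
* **Facilities** — exact per-level (public, private) counts; the default
  registry has 292 facilities (13 hospitals of which 10 public; 29 %
  public overall), with public facilities split ~24 %/5 % between
  government and faith-based sectors. Placement follows population density
  to the `clustering` power and snaps to the nearest road, so facilities
  always sit on passable cells.
* **Population** — a mixture of Gaussian clusters over a uniform floor,
  normalized so the raster totals `total_wocba` exactly (default 10 000, a
  desk-scale stand-in for a metropolitan WoCBA population).
* **RWI points** — a jittered grid at `rwi_spacing` (default 300 m,
  scaled down in proportion to the synthetic extent) carrying a linear
  west–east wealth gradient plus Gaussian noise; with noise 0 the gradient
  is the exact ground truth.
* **Urbanicity** — smoothed population density thresholded at configured
  quantiles into 7 ordered bands (very low density … city), so band
  ordering by density is true by construction.
* **Trajectories** — trips traverse whole road segments at the class's
  ground-truth mean speed. Sample times are the union of the regular
  `sampling_dt` ticks and the exact vertex-passage moments, so consecutive
  points always lie on one straight piece and chord length equals distance
  travelled — this is what makes noise-free speed recovery exact to float
  precision rather than merely approximate. GPS noise is i.i.d. Gaussian
  per coordinate.

All generators are pure functions of (inputs, seed); the seed is mandatory.

What the synthetic data does *not* emulate: traffic congestion by time of
day, one-way streets and turn restrictions, bridges over water, seasonal
flooding, facility bypassing behaviour, and the native (coarser)
resolution of real RWI rasters. Passing tests therefore demonstrate the
correctness of the computational chain and its invariants, not the realism
of any particular speed or coverage figure for a real city.

## Numerical choices

* Travel time is float64 internally, written as minutes with 9 significant
  digits (round-trips float32 exactly); +inf encodes "unreachable" and NaN
  "outside the populated mask", distinctly.
* Scenario dominance (min ≤ mean ≤ max per class) is validated on every
  `SpeedTable`, which makes scenario monotonicity of travel time a theorem
  rather than a hope; water must be 0 in all three columns.
* Rasterization and zone assignment tie-breaks are deterministic (highest
  mean speed; lowest zone id), so reruns are byte-identical.
* Degenerate inputs fail loudly: empty facility strata, all-zero weights,
  unknown class codes, non-finite slopes, unsorted thresholds.

## Problem sizes

The bundled analyses and tests run at desk scale: 30–60 cell grids for
landscape-level checks, ≤12×12 grids (100 seeds) for brute-force oracle
equivalence, and a 60×60 full-design run in the acceptance script. The
engine itself is O(E log V) in grid cells and handles metropolitan-scale
grids (millions of cells) in minutes; sizes here were chosen so the full
verification chain — including the deliberately slow edge-by-edge oracle —
remains quick to rerun.

## Known limitations

* No explicit mode-change modelling (walk → drive legs); the per-cell
  regime handles the transition implicitly, which understates waiting and
  parking time.
* Nearest-facility assumption: bypassing and referral chains are out of
  scope.
* The minimum/maximum scenario columns are absolute observed extremes, not
  trimmed percentiles, so single-observation glitches below the outlier
  cap can widen the scenario band.
* Equivalence with any particular GIS cost-distance implementation is not
  claimed; the contract is the explicit move-graph definition above.
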