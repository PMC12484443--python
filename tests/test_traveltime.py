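"""Multi-source least-cost accumulation: closed forms, oracle equivalence,
monotonicity."""

import numpy as np
import pandas as pd
import pytest

from accessim.friction import SpeedRaster
from accessim.grid import GridSpec, Raster
from accessim.landscape import DEFAULT_FACILITY_COUNTS, gen_facilities
from accessim.speeds import default_speed_table
from accessim.traveltime import accumulate, run_matrix, select_stratum
from accessim.vectors import FacilityRegistry

from conftest import uniform_speed_raster


def nx_oracle(speed, dem, source_cells, connectivity=8):
    """Independent brute-force shortest path on the explicit move graph,
    built edge by edge with networkx."""
    import networkx as nx

    spec = speed.grid
    offs = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)]
    if connectivity == 16:
        offs += [(1, 2), (2, 1), (-1, 2), (-2, 1), (1, -2), (2, -1), (-1, -2),
                 (-2, -1)]
    elev = np.zeros(spec.shape) if dem is None else np.asarray(dem.data, float)
    G = nx.DiGraph()
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            if speed.speed[r, c] <= 0:
                continue
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < spec.n_rows and 0 <= cc < spec.n_cols):
                    continue
                if speed.speed[rr, cc] <= 0:
                    continue
                d = spec.cell_size * np.hypot(dr, dc)
                s = (elev[rr, cc] - elev[r, c]) / d
                fac = np.exp(-3.5 * abs(s + 0.05)) / np.exp(-3.5 * 0.05)
                va = speed.speed[r, c] * (fac if speed.is_walking[r, c] else 1.0)
                vb = speed.speed[rr, cc] * (fac if speed.is_walking[rr, cc] else 1.0)
                G.add_edge((r, c), (rr, cc), weight=d * (0.5 / va + 0.5 / vb))
    rev = G.reverse()
    for s in source_cells:
        rev.add_node(s)
    dist = nx.multi_source_dijkstra_path_length(rev, set(source_cells))
    out = np.full(spec.shape, np.inf)
    for (r, c), v in dist.items():
        out[r, c] = v / 60.0
    return out


def sources_xy(spec, cells):
    r = np.array([c[0] for c in cells])
    c = np.array([c[1] for c in cells])
    x, y = spec.cell_center(r, c)
    return np.column_stack([x, y])


class TestClosedForms:
    def test_three_cell_walk_at_five_kmh(self):
        # 1x3 grid, 30 m cells, 5 km/h everywhere: far cell is 60 m away
        spec = GridSpec(1, 3, cell_size=30.0)
        sr = uniform_speed_raster(spec, 5.0 / 3.6)
        tt = accumulate(sr, None, sources_xy(spec, [(0, 0)]))
        assert tt.data[0, 0] == 0.0
        assert tt.data[0, 2] == pytest.approx(0.72, rel=1e-9)

    def test_source_cell_is_zero(self):
        spec = GridSpec(5, 5, cell_size=30.0)
        sr = uniform_speed_raster(spec, 1.0)
        tt = accumulate(sr, None, sources_xy(spec, [(2, 3)]))
        assert tt.data[2, 3] == 0.0

    def test_uniform_friction_equals_octile_distance(self):
        spec = GridSpec(50, 50, cell_size=30.0)
        v = 1.4
        sr = uniform_speed_raster(spec, v)
        src = (17, 31)
        tt = accumulate(sr, None, sources_xy(spec, [src]))
        rows, cols = np.meshgrid(np.arange(50), np.arange(50), indexing="ij")
        dr = np.abs(rows - src[0])
        dc = np.abs(cols - src[1])
        octile = spec.cell_size * (np.maximum(dr, dc) - np.minimum(dr, dc)
                                   + np.sqrt(2) * np.minimum(dr, dc))
        np.testing.assert_allclose(tt.data, octile / v / 60.0, rtol=1e-9)


class TestOracleEquivalence:
    @pytest.mark.parametrize("connectivity", [8, 16])
    def test_random_grids_match_networkx(self, connectivity):
        rng = np.random.default_rng(1234)
        for _ in range(20):
            nr, nc = rng.integers(3, 13, size=2)
            spec = GridSpec(int(nr), int(nc), cell_size=30.0)
            v = rng.uniform(0.3, 8.0, size=spec.shape)
            v[rng.random(spec.shape) < 0.15] = 0.0  # barriers
            walk = rng.random(spec.shape) < 0.5
            dem = Raster(spec, rng.uniform(0, 40, size=spec.shape))
            sr = SpeedRaster(spec, v, walk)
            passable = np.argwhere(v > 0)
            if len(passable) == 0:
                continue
            k = int(rng.integers(1, 4))
            cells = [tuple(passable[i]) for i in
                     rng.choice(len(passable), size=min(k, len(passable)),
                                replace=False)]
            tt = accumulate(sr, dem, sources_xy(spec, cells),
                            connectivity=connectivity)
            expected = nx_oracle(sr, dem, cells, connectivity)
            np.testing.assert_allclose(tt.data, expected, rtol=1e-9)


class TestBarriersAndSnapping:
    def test_water_ring_makes_interior_unreachable(self):
        spec = GridSpec(7, 7, cell_size=30.0)
        v = np.full(spec.shape, 1.0)
        v[2:5, 2:5] = 1.0
        v[2, 2:5] = v[4, 2:5] = v[2:5, 2] = v[2:5, 4] = 0.0  # ring
        sr = SpeedRaster(spec, v, np.ones(spec.shape, bool))
        tt = accumulate(sr, None, sources_xy(spec, [(0, 0)]))
        assert np.isinf(tt.data[3, 3])
        assert np.isfinite(tt.data[0, 6])

    def test_facility_on_barrier_snaps_to_neighbour(self):
        spec = GridSpec(5, 5, cell_size=30.0)
        v = np.full(spec.shape, 1.0)
        v[2, 2] = 0.0
        sr = SpeedRaster(spec, v, np.ones(spec.shape, bool))
        tt = accumulate(sr, None, sources_xy(spec, [(2, 2)]))
        assert np.isfinite(tt.data[0, 0])
        assert (tt.data[np.isfinite(tt.data)] == 0).sum() == 1  # snapped source

    def test_all_barrier_grid_is_an_error(self):
        spec = GridSpec(3, 3, cell_size=30.0)
        sr = SpeedRaster(spec, np.zeros(spec.shape),
                         np.ones(spec.shape, bool))
        with pytest.raises(ValueError, match="passable"):
            accumulate(sr, None, sources_xy(spec, [(1, 1)]))

    def test_triangle_property_extra_facility_never_hurts(self):
        rng = np.random.default_rng(7)
        spec = GridSpec(12, 12, cell_size=30.0)
        v = rng.uniform(0.5, 5.0, size=spec.shape)
        sr = SpeedRaster(spec, v, np.ones(spec.shape, bool))
        tt1 = accumulate(sr, None, sources_xy(spec, [(2, 2)]))
        tt2 = accumulate(sr, None, sources_xy(spec, [(2, 2), (9, 9)]))
        assert (tt2.data <= tt1.data + 1e-12).all()


@pytest.fixture(scope="module")
def registry():
    spec = GridSpec(50, 50, cell_size=30.0)
    return gen_facilities(spec, DEFAULT_FACILITY_COUNTS, seed=99)


class TestSelectStratum:
    @pytest.mark.parametrize("stratum,n", [
        ("all", 292), ("public", 84), ("hospitals", 13), ("public_hospitals", 10),
    ])
    def test_stratum_counts(self, registry, stratum, n):
        assert len(select_stratum(registry, stratum)) == n

    def test_empty_stratum_is_an_error(self):
        reg = FacilityRegistry(pd.DataFrame([
            dict(facility_id="F0", x=10.0, y=10.0, level="clinic",
                 sector="private"),
        ]))
        with pytest.raises(ValueError, match="no facilities"):
            select_stratum(reg, "public")

    def test_unknown_stratum_rejected(self, registry):
        with pytest.raises(ValueError, match="unknown stratum"):
            select_stratum(registry, "ngo")


class TestRunMatrix:
    def test_full_design_yields_twelve_surfaces(self, landscape50):
        table = default_speed_table()
        surfaces = run_matrix(
            landscape50["roads"], landscape50["landcover"], landscape50["dem"],
            table, landscape50["registry"],
        )
        assert len(surfaces) == 12
        assert {k[0] for k in surfaces} == {"all", "public", "hospitals",
                                            "public_hospitals"}

    def test_single_pair_yields_one_surface(self, landscape50):
        surfaces = run_matrix(
            landscape50["roads"], landscape50["landcover"], landscape50["dem"],
            default_speed_table(), landscape50["registry"],
            strata=["all"], scenarios=["average"],
        )
        assert list(surfaces) == [("all", "average")]

    def test_deterministic_across_runs(self, landscape50):
        args = (landscape50["roads"], landscape50["landcover"],
                landscape50["dem"], default_speed_table(),
                landscape50["registry"])
        a = run_matrix(*args, strata=["hospitals"], scenarios=["minimum"])
        b = run_matrix(*args, strata=["hospitals"], scenarios=["minimum"])
        np.testing.assert_array_equal(
            a[("hospitals", "minimum")].data, b[("hospitals", "minimum")].data
        )

    def test_scenario_and_stratum_monotonicity(self, landscape50):
        surfaces = run_matrix(
            landscape50["roads"], landscape50["landcover"], landscape50["dem"],
            default_speed_table(), landscape50["registry"],
            strata=["all", "hospitals"],
        )
        for stratum in ("all", "hospitals"):
            lo = surfaces[(stratum, "maximum")].data
            mid = surfaces[(stratum, "average")].data
            hi = surfaces[(stratum, "minimum")].data
            assert (lo <= mid + 1e-9).all() and (mid <= hi + 1e-9).all()
        for scenario in ("minimum", "average", "maximum"):
            assert (surfaces[("all", scenario)].data
                    <= surfaces[("hospitals", scenario)].data + 1e-9).all()
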