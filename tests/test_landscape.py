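"""Synthetic landscape generators: determinism, conservation, closure,
ground-truth retention."""

import numpy as np
import pytest

from accessim.classes import LANDCOVER_CODES
from accessim.grid import GridSpec
from accessim.landscape import (
    DEFAULT_FACILITY_COUNTS,
    LandscapeConfig,
    gen_facilities,
    gen_landscape,
    gen_population_rwi_urbanicity,
    gen_trajectories,
)
from accessim.speeds import default_speed_table
from accessim.traveltime import select_stratum


class TestGenLandscape:
    def test_deterministic_under_fixed_seed(self, spec50):
        a = gen_landscape(spec50, LandscapeConfig(), seed=5)
        b = gen_landscape(spec50, LandscapeConfig(), seed=5)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].data, b[1].data)
        assert [s.coords for s in a[2].segments] == [s.coords for s in b[2].segments]

    def test_seed_is_mandatory(self, spec50):
        with pytest.raises(ValueError, match="seed"):
            gen_landscape(spec50, LandscapeConfig())

    def test_fractions_must_sum_to_one(self, spec50):
        cfg = LandscapeConfig()
        cfg.landcover_fractions = {"water": 0.5, "crops": 0.4}
        with pytest.raises(ValueError, match="sum"):
            gen_landscape(spec50, cfg, seed=1)

    def test_zero_water_fraction_gives_no_barrier_cells(self, spec50):
        cfg = LandscapeConfig()
        cfg.landcover_fractions = dict(cfg.landcover_fractions)
        cfg.landcover_fractions["water"] = 0.0
        cfg.landcover_fractions["crops"] += 0.08
        _, lc, _, _ = gen_landscape(spec50, cfg, seed=2)
        assert (lc.data == LANDCOVER_CODES["water"]).sum() == 0

    def test_water_share_matches_configured_fraction(self):
        spec = GridSpec(100, 100, cell_size=30.0)
        cfg = LandscapeConfig()
        cfg.landcover_fractions = dict(cfg.landcover_fractions)
        cfg.landcover_fractions["water"] = 0.10
        cfg.landcover_fractions["built_area"] -= 0.02
        _, lc, _, _ = gen_landscape(spec, cfg, seed=3)
        share = (lc.data == LANDCOVER_CODES["water"]).mean()
        assert 0.08 <= share <= 0.12

    def test_all_fractions_honoured_within_two_points(self, spec50):
        cfg = LandscapeConfig()
        _, lc, _, _ = gen_landscape(spec50, cfg, seed=4)
        for name, frac in cfg.landcover_fractions.items():
            share = (lc.data == LANDCOVER_CODES[name]).mean()
            assert abs(share - frac) <= 0.02, name

    def test_roads_span_extent_and_stay_inside(self, spec50):
        _, _, roads, _ = gen_landscape(spec50, LandscapeConfig(), seed=6)
        xmin, ymin, xmax, ymax = spec50.extent
        xs = np.concatenate([[p[0] for p in s.coords] for s in roads.segments])
        ys = np.concatenate([[p[1] for p in s.coords] for s in roads.segments])
        assert xs.min() >= xmin and xs.max() <= xmax
        assert ys.min() >= ymin and ys.max() <= ymax
        # the backbone reaches both west and east edges
        assert xs.min() < xmin + spec50.cell_size
        assert xs.max() > xmax - spec50.cell_size

    def test_zone_levels_partition_extent(self, spec50):
        from accessim.coverage import zone_index_raster

        _, _, _, zones = gen_landscape(spec50, LandscapeConfig(), seed=7)
        for level in ("commune", "arrondissement", "departement", "health_zone"):
            zr = zone_index_raster(zones, level, spec50)
            assert (zr.data >= 0).all(), level  # every cell in exactly one zone

    def test_dem_is_finite(self, spec50):
        dem, _, _, _ = gen_landscape(spec50, LandscapeConfig(), seed=8)
        assert np.isfinite(dem.data).all()


class TestGenFacilities:
    def test_default_registry_structure(self, spec50):
        reg = gen_facilities(spec50, DEFAULT_FACILITY_COUNTS, seed=1)
        assert len(reg) == 292
        assert reg.n_public() == 84
        assert reg.n_private() == 208
        assert len(select_stratum(reg, "hospitals")) == 13
        assert len(select_stratum(reg, "public_hospitals")) == 10

    def test_single_public_hospital(self, spec50):
        reg = gen_facilities(spec50, {"hospital": (1, 0)}, seed=2)
        assert len(reg) == 1
        row = reg.table.iloc[0]
        assert row.level == "hospital" and row.sector.startswith("public")

    def test_zero_total_is_an_error(self, spec50):
        with pytest.raises(ValueError, match="at least one"):
            gen_facilities(spec50, {"hospital": (0, 0)}, seed=3)

    def test_coordinates_inside_extent(self, landscape50):
        xy = landscape50["registry"].xy
        xmin, ymin, xmax, ymax = landscape50["spec"].extent
        assert (xy[:, 0] >= xmin).all() and (xy[:, 0] <= xmax).all()
        assert (xy[:, 1] >= ymin).all() and (xy[:, 1] <= ymax).all()

    def test_clustering_pulls_facilities_to_dense_cells(self, spec50):
        pop, _, _ = gen_population_rwi_urbanicity(spec50, seed=20)
        dens = np.asarray(pop.data, float)
        counts = {"clinic": (0, 120)}

        def mean_density_at(clustering, seed):
            reg = gen_facilities(spec50, counts, clustering=clustering,
                                 seed=seed, pop=pop)
            r, c = spec50.cell_of(reg.xy[:, 0], reg.xy[:, 1])
            return dens[np.clip(r, 0, 49), np.clip(c, 0, 49)].mean()

        weak = np.mean([mean_density_at(0.2, s) for s in range(5)])
        strong = np.mean([mean_density_at(3.0, s) for s in range(5)])
        assert strong > weak


class TestPopulationRwiUrbanicity:
    def test_population_total_is_conserved(self, spec50):
        cfg = LandscapeConfig()
        cfg.total_wocba = 10000.0
        pop, _, _ = gen_population_rwi_urbanicity(spec50, cfg, seed=1)
        assert abs(pop.data.sum() - 10000.0) / 10000.0 < 1e-3
        assert (pop.data >= 0).all()

    def test_pure_gradient_rwi_increases_eastward(self, spec50):
        cfg = LandscapeConfig()
        cfg.rwi_noise_sd = 0.0
        _, rwi, _ = gen_population_rwi_urbanicity(spec50, cfg, seed=2)
        order = np.argsort(rwi.x)
        assert (np.diff(rwi.rwi[order]) >= 0).all()

    def test_rwi_points_inside_extent(self, spec50):
        _, rwi, _ = gen_population_rwi_urbanicity(spec50, seed=3)
        xmin, ymin, xmax, ymax = spec50.extent
        assert ((rwi.x >= xmin) & (rwi.x < xmax)).all()
        assert ((rwi.y >= ymin) & (rwi.y < ymax)).all()

    def test_spacing_too_large_raises(self, spec50):
        cfg = LandscapeConfig()
        cfg.rwi_spacing = 10 * spec50.width
        with pytest.raises(ValueError, match="fewer than 5"):
            gen_population_rwi_urbanicity(spec50, cfg, seed=4)

    def test_urbanicity_bands_ordered_by_density(self, spec50):
        from scipy.ndimage import gaussian_filter

        cfg = LandscapeConfig()
        pop, _, urb = gen_population_rwi_urbanicity(spec50, cfg, seed=5)
        smoothed = gaussian_filter(np.asarray(pop.data, float),
                                   sigma=cfg.urbanicity_smoothness)
        bands = np.asarray(urb.data)
        for b in range(bands.max()):
            hi = smoothed[bands == b + 1]
            lo = smoothed[bands == b]
            if hi.size and lo.size:
                assert hi.min() >= lo.max() - 1e-12


class TestGenTrajectories:
    def test_noise_free_speeds_equal_ground_truth(self, landscape50):
        roads = landscape50["roads"]
        truth = default_speed_table()
        trips = gen_trajectories(roads, truth, n_trips=3, seed=1)
        cls = {s.segment_id: s.road_class for s in roads.segments}
        for trip, seg in zip(trips, sorted(roads.segments,
                                           key=lambda s: s.segment_id)):
            v = truth.speed_kmh("road", cls[seg.segment_id], "average") / 3.6
            d = np.hypot(np.diff(trip.x), np.diff(trip.y))
            np.testing.assert_allclose(d / np.diff(trip.t), v, rtol=1e-9)

    def test_point_count_on_straight_kilometre(self):
        from accessim.speeds import SpeedTable, default_speed_table
        from accessim.vectors import RoadNetwork, RoadSegment

        # 1000 m trunk at 20 km/h, dt 1 s -> 180 s traverse, 181 points
        seg = RoadSegment(0, "trunk", ((0.0, 0.0), (1000.0, 0.0)))
        table = default_speed_table()
        table.table.loc[table.table["class"] == "trunk", "mean"] = 20.0
        table = SpeedTable(table.table)
        trips = gen_trajectories(RoadNetwork([seg]), table, n_trips=1,
                                 sampling_dt=1.0, seed=1)
        assert len(trips[0]) == 181
        assert trips[0].t[-1] == pytest.approx(180.0)

    def test_same_seed_identical_trajectories(self, landscape50):
        roads = landscape50["roads"]
        truth = default_speed_table()
        a = gen_trajectories(roads, truth, 5, gps_noise_sd=3.0, seed=9)
        b = gen_trajectories(roads, truth, 5, gps_noise_sd=3.0, seed=9)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x, tb.x)
            np.testing.assert_array_equal(ta.t, tb.t)

    def test_nonpositive_sampling_dt_rejected(self, landscape50):
        with pytest.raises(ValueError, match="sampling_dt"):
            gen_trajectories(landscape50["roads"], default_speed_table(),
                             1, sampling_dt=0.0, seed=1)

    def test_missing_class_in_truth_table_rejected(self, landscape50):
        import pandas as pd

        from accessim.speeds import SpeedTable

        truth = default_speed_table()
        trimmed = SpeedTable(
            pd.DataFrame(truth.table[truth.table["class"] != "trunk"])
        )
        with pytest.raises(ValueError, match="trunk"):
            gen_trajectories(landscape50["roads"], trimmed, 1, seed=1)
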