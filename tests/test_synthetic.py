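import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely import contains_xy

from nesttrack import synthetic as syn
from nesttrack._geo import haversine_km

ZERO_SD = {c: 0.0 for c in ["3", "2", "1", "0", "A", "B", "Z"]}


class TestIsland:
    def test_regions_present_and_valid(self, island):
        kinds = [r.kind for r in island.regions]
        assert kinds.count("eez") >= 2
        assert "land" in kinds and "reserve" in kinds
        assert all(r.geometry.is_valid for r in island.regions)

    def test_reserve_marine_breadth_two_km(self, island):
        from nesttrack._geo import AzimuthalEqualArea, project_geometry
        land = island.by_kind("land")[0].geometry
        reserve = island.by_kind("reserve")[0].geometry
        c = land.centroid
        proj = AzimuthalEqualArea(c.x, c.y)
        from shapely.geometry import Point
        marine = project_geometry(reserve.difference(land), proj)
        coast = project_geometry(land, proj).boundary
        # the marine part's farthest vertex from shore sits at the breadth
        dists = [coast.distance(Point(xy)) for xy in marine.exterior.coords]
        assert max(dists) == pytest.approx(2.0, abs=0.15)

    def test_eez_polygons_disjoint(self, island):
        eezs = [r.geometry for r in island.by_kind("eez")]
        assert eezs[0].intersection(eezs[1]).area == pytest.approx(0.0, abs=1e-12)


class TestSimulateAnimal:
    def test_deterministic_under_seed_and_index(self, island):
        cfg = syn.SimConfig(seed=4)
        a = syn.simulate_animal(cfg, island, 2)
        b = syn.simulate_animal(cfg, island, 2)
        assert np.array_equal(a.lon, b.lon) and np.array_equal(a.lat, b.lat)
        assert a.nesting_events == b.nesting_events
        assert a.migration_start == b.migration_start

    def test_successful_event_durations_within_range(self, island):
        cfg = syn.SimConfig(seed=9, n_clutches_range=(3, 3), failed_fraction=0.0)
        tr = syn.simulate_animal(cfg, island, 0)
        assert len(tr.nesting_events) == 3
        for s, e, outcome in tr.nesting_events:
            minutes = (e - s).total_seconds() / 60.0
            assert outcome == "successful"
            assert 72.0 <= minutes <= 187.0

    def test_events_on_land_and_migration_after_last_event(self, island):
        cfg = syn.SimConfig(seed=9)
        land = island.by_kind("land")[0].geometry
        tr = syn.simulate_animal(cfg, island, 1)
        assert tr.migration_start >= tr.nesting_events[-1][1]
        mid_idx = [np.argmin(np.abs(tr.times - (s + (e - s) / 2)))
                   for s, e, _ in tr.nesting_events]
        assert contains_xy(land, tr.lon[mid_idx], tr.lat[mid_idx]).all()

    def test_south_america_group_exceeds_group_threshold(self, island):
        # lower-bound oracle: >= 100 d of directed movement at 40 km/d
        cfg = syn.SimConfig(seed=2,
                            migration_group_probs={"south_america": 1.0},
                            migration_speed=40.0,
                            directed_days_range={"south_america": (100.0, 110.0)})
        tr = syn.simulate_animal(cfg, island, 0)
        d = haversine_km(tr.origin[0], tr.origin[1], tr.lon, tr.lat)
        assert tr.migration_group == "south_america"
        assert d.max() > 3200.0

    def test_internesting_loops_bounded_by_trip_max(self, island):
        cfg = syn.SimConfig(seed=6)
        tr = syn.simulate_animal(cfg, island, 3)
        pre = tr.times <= tr.migration_start
        d = haversine_km(tr.origin[0], tr.origin[1], tr.lon[pre], tr.lat[pre])
        assert d.max() <= cfg.internesting_trip_max_km * 1.15  # bridge wiggle


class TestObserveArgos:
    def test_zero_noise_fixes_lie_on_truth_path(self, island):
        cfg = syn.SimConfig(seed=3, argos_error_sd_km=dict(ZERO_SD))
        tr = syn.simulate_animal(cfg, island, 0)
        obs = syn.observe_argos(tr, cfg)
        tsec = (tr.times - tr.times[0]).total_seconds().to_numpy()
        osec = (pd.DatetimeIndex(obs["timestamp"]) - tr.times[0]).total_seconds()
        elon = np.interp(osec, tsec, tr.lon)
        elat = np.interp(osec, tsec, tr.lat)
        # fix times are rounded to 1 s; slack covers within-step movement
        assert np.max(np.abs(obs["lon"] - elon)) < 1e-4
        assert np.max(np.abs(obs["lat"] - elat)) < 1e-4

    def test_rms_radial_error_matches_isotropic_sd(self, island):
        sd = 0.4
        cfg = syn.SimConfig(seed=3, fix_rate_per_day=400.0,
                            argos_class_probs={"3": 1.0},
                            argos_error_sd_km={**ZERO_SD, "3": sd},
                            ars_days=60.0)
        tr = syn.simulate_animal(cfg, island, 0)
        obs = syn.observe_argos(tr, cfg)
        tsec = (tr.times - tr.times[0]).total_seconds().to_numpy()
        osec = (pd.DatetimeIndex(obs["timestamp"]) - tr.times[0]).total_seconds()
        err = haversine_km(np.interp(osec, tsec, tr.lon),
                           np.interp(osec, tsec, tr.lat),
                           obs["lon"].to_numpy(), obs["lat"].to_numpy())
        n = len(err)
        assert n > 5000
        rms = np.sqrt(np.mean(err ** 2))
        assert rms == pytest.approx(sd * np.sqrt(2), rel=0.05)

    def test_class_frequencies_match_probabilities(self, island):
        cfg = syn.SimConfig(seed=3, fix_rate_per_day=60.0)
        tr = syn.simulate_animal(cfg, island, 0)
        obs = syn.observe_argos(tr, cfg)
        n = len(obs)
        counts = obs["loc_class"].value_counts()
        for c, p in cfg.argos_class_probs.items():
            k = counts.get(c, 0)
            assert stats.binomtest(k, n, p).pvalue > 1e-4

    def test_bad_class_error_ordering_rejected(self):
        with pytest.raises(ValueError, match="class 0"):
            syn.SimConfig(argos_error_sd_km={**syn.SimConfig().argos_error_sd_km,
                                             "0": 1.0})


class TestObserveDrytime:
    def _truth_with_event(self, island, start_min, dur_min):
        cfg = syn.SimConfig(seed=1)
        tr = syn.simulate_animal(cfg, island, 0)
        t0 = tr.times[0].floor("h")
        s = t0 + pd.Timedelta(minutes=start_min)
        return cfg, syn.TruthRecord(
            animal_id="x", times=tr.times, lon=tr.lon, lat=tr.lat,
            on_land=tr.on_land,
            nesting_events=[(s, s + pd.Timedelta(minutes=dur_min), "successful")],
            migration_start=tr.migration_start, migration_group="central_atlantic",
            tagging_time=tr.tagging_time, origin=tr.origin)

    def test_event_overlap_split_across_hours(self, island):
        # 80-min event from minute 20: 40 min in each of two hours -> >= 66 %
        cfg, truth = self._truth_with_event(island, 20, 80)
        dry = syn.observe_drytime(truth, cfg)
        v = dry["pct_dry"].to_numpy()
        assert v[0] >= 40 / 60 * 100 - 1e-9
        assert v[1] >= 40 / 60 * 100 - 1e-9

    def test_no_nesting_no_background_is_all_zero(self, island):
        cfg = syn.SimConfig(seed=1, drytime_background_max=0.0)
        tr = syn.simulate_animal(cfg, island, 0)
        truth = syn.TruthRecord("x", tr.times, tr.lon, tr.lat, tr.on_land,
                                [], tr.migration_start, "central_atlantic",
                                tr.tagging_time, tr.origin)
        dry = syn.observe_drytime(truth, cfg)
        assert (dry["pct_dry"] == 0).all()

    def test_background_bounded(self, island):
        cfg = syn.SimConfig(seed=1)
        tr = syn.simulate_animal(cfg, island, 0)
        truth = syn.TruthRecord("x", tr.times, tr.lon, tr.lat, tr.on_land,
                                [], tr.migration_start, "central_atlantic",
                                tr.tagging_time, tr.origin)
        dry = syn.observe_drytime(truth, cfg)
        assert dry["pct_dry"].max() <= cfg.drytime_background_max + 1e-9


class TestEffort:
    def test_purse_seine_concentrated_in_eezs(self, island):
        cfg = syn.SimConfig(seed=1)
        grid = syn.simulate_effort(island, cfg, seed=1)
        eezs = [r.geometry for r in island.by_kind("eez")]
        df = grid.cells[grid.cells["gear"] == "purse_seine"]
        half = grid.cell_size / 2
        inside = contains_xy(eezs[0].union(eezs[1]),
                             df["lon"].to_numpy() + half,
                             df["lat"].to_numpy() + half)
        assert df[inside]["hours"].sum() > df[~inside]["hours"].sum()

    def test_zero_intensity_empty_and_determinism(self, island):
        cfg = syn.SimConfig(seed=1)
        empty = syn.simulate_effort(island, cfg, seed=1, intensity=0.0)
        assert len(empty.cells) == 0
        a = syn.simulate_effort(island, cfg, seed=5, cells_per_gear=40)
        b = syn.simulate_effort(island, cfg, seed=5, cells_per_gear=40)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_all_hours_non_negative_on_grid(self, island):
        cfg = syn.SimConfig(seed=1)
        grid = syn.simulate_effort(island, cfg, seed=2, cells_per_gear=40)
        assert (grid.cells["hours"] >= 0).all()
        r = grid.cells["lat"] / grid.cell_size
        assert np.allclose(r, np.round(r), atol=1e-6)
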