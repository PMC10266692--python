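import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nesttrack import synthetic as syn
from nesttrack._geo import haversine_km, track_speeds_ms
from nesttrack.preprocessing import (FilterConfig, _kalman, apply_filters,
                                     ctcrw_matrices, filter_classes,
                                     filter_on_land, filter_speed, regularize)


def locs_frame(times, lon, lat, classes):
    return pd.DataFrame({
        "animal_id": "t1",
        "timestamp": pd.DatetimeIndex(times, tz="UTC"),
        "lon": np.asarray(lon, dtype=float),
        "lat": np.asarray(lat, dtype=float),
        "loc_class": list(classes),
    })


class TestClassFilter:
    def test_default_drops_0_and_z_keeps_a_b(self):
        t = pd.date_range("2019-01-01", periods=5, freq="1h")
        df = locs_frame(t, [8] * 5, [3] * 5, ["3", "0", "B", "Z", "A"])
        out = filter_classes(df, FilterConfig())
        assert list(out["loc_class"]) == ["3", "B", "A"]

    def test_empty_drop_set_is_identity(self):
        t = pd.date_range("2019-01-01", periods=3, freq="1h")
        df = locs_frame(t, [8, 8.1, 8.2], [3, 3, 3], ["0", "Z", "B"])
        out = filter_classes(df, FilterConfig(drop_classes=frozenset()))
        assert len(out) == 3

    def test_all_dropped_warns(self):
        t = pd.date_range("2019-01-01", periods=10, freq="1h")
        df = locs_frame(t, [8] * 10, [3] * 10, ["Z"] * 10)
        with pytest.warns(UserWarning, match="all .* dropped"):
            out = filter_classes(df, FilterConfig())
        assert len(out) == 0


class TestSpeedFilter:
    def test_sixty_km_in_one_hour_drops_later_fix(self):
        # 60 km in 3600 s = 16.7 m/s > 15
        t = pd.date_range("2019-01-01", periods=2, freq="1h")
        df = locs_frame(t, [8.0, 8.0], [3.0, 3.0 + 60.0 / 111.1949], ["3", "3"])
        v = track_speeds_ms(df["timestamp"], df["lon"].to_numpy(),
                            df["lat"].to_numpy())[0]
        assert v > 15.0
        out = filter_speed(df, FilterConfig())
        assert len(out) == 1 and out["timestamp"].iloc[0] == t[0].tz_localize("UTC")

    def test_stationary_track_identity(self):
        t = pd.date_range("2019-01-01", periods=6, freq="2h")
        df = locs_frame(t, [8] * 6, [3] * 6, ["3"] * 6)
        assert len(filter_speed(df, FilterConfig())) == 6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_postcondition_and_idempotence_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        t = pd.date_range("2019-01-01", periods=n, freq="1h")
        lon = 8 + np.cumsum(rng.normal(0, 0.2, n))
        lat = 3 + np.cumsum(rng.normal(0, 0.2, n))
        df = locs_frame(t, lon, lat, ["3"] * n)
        out = filter_speed(df, FilterConfig())
        if len(out) >= 2:
            v = track_speeds_ms(out["timestamp"], out["lon"].to_numpy(),
                                out["lat"].to_numpy())
            assert np.all(v <= 15.0 + 1e-9)
        again = filter_speed(out, FilterConfig())
        pd.testing.assert_frame_equal(out, again)


class TestLandFilter:
    def test_interior_point_scoping_and_boundary(self, island):
        land = island.by_kind("land")[0].geometry
        c = land.centroid
        boundary_pt = land.exterior.coords[0]
        t = pd.date_range("2019-01-01", periods=3, freq="1D")
        df = locs_frame(t, [c.x, c.x, boundary_pt[0]],
                        [c.y, c.y, boundary_pt[1]], ["3"] * 3)
        # window covers only the first point: second (same place, later) kept
        out = filter_on_land(df, land, (t[0], t[0] + pd.Timedelta("12h")))
        assert len(out) == 2
        # boundary point retained even inside the window (strict interior)
        out_all = filter_on_land(df, land, None)
        assert boundary_pt[0] in out_all["lon"].to_numpy()

    def test_filters_idempotent(self, island):
        cfg = syn.SimConfig(seed=8)
        tr = syn.simulate_animal(cfg, island, 0)
        obs = syn.observe_argos(tr, cfg)
        land = island.by_kind("land")[0].geometry
        once = apply_filters(obs, FilterConfig(), land)
        twice = apply_filters(once, FilterConfig(), land)
        pd.testing.assert_frame_equal(once, twice)


class TestRegularize:
    def test_straight_line_noise_free_interpolated_exactly(self):
        n = 30
        t = pd.date_range("2019-01-01", periods=n, freq="137min", tz="UTC")
        lon = 8.0 + 0.01 * np.arange(n)
        lat = 3.0 + 0.005 * np.arange(n)
        df = locs_frame(t, lon, lat, ["3"] * n)
        tr = regularize(df, "4h", {"3": 0.0})
        tsec = (t - t[0]).total_seconds()
        gsec = (tr.times - t[0]).total_seconds()
        assert np.max(np.abs(tr.lon - np.interp(gsec, tsec, lon))) < 1e-6
        assert np.max(np.abs(tr.lat - np.interp(gsec, tsec, lat))) < 1e-6

    def test_grid_gaps_exactly_four_hours(self, island):
        cfg = syn.SimConfig(seed=8)
        tr = syn.simulate_animal(cfg, island, 0)
        obs = syn.observe_argos(tr, cfg)
        f = apply_filters(obs, FilterConfig(), island.by_kind("land")[0].geometry)
        track = regularize(f, "4h")
        assert (np.diff(track.times.asi8) == 4 * 3600 * 10 ** 9).all()

    def test_smoother_equals_dense_gls_solve(self):
        # oracle: joint-Gaussian posterior mean via dense covariance algebra
        rng = np.random.default_rng(3)
        n = 12
        th = np.sort(rng.uniform(0, 48, n))
        th[0] = 0.0
        beta, s2, p0 = 0.2, 4.0, 100.0
        y = np.column_stack([np.cumsum(rng.normal(0, 2, n)),
                             np.cumsum(rng.normal(0, 2, n))])
        r = rng.uniform(0.3, 2.0, n)
        _, pos, _ = _kalman(th, y, r, beta, s2, p0, smooth=True)
        T, Q = ctcrw_matrices(beta, s2, np.diff(th))
        C = np.zeros((2 * n, 2 * n))
        M = np.zeros((2 * n, 2))
        C[:2, :2] = np.diag([p0, s2 / (2 * beta)])
        M[0] = y[0]
        for k in range(1, n):
            Tk = T[k - 1]
            M[2 * k:2 * k + 2] = Tk @ M[2 * (k - 1):2 * k]
            for j in range(k):
                blk = Tk @ C[2 * (k - 1):2 * k, 2 * j:2 * j + 2]
                C[2 * k:2 * k + 2, 2 * j:2 * j + 2] = blk
                C[2 * j:2 * j + 2, 2 * k:2 * k + 2] = blk.T
            C[2 * k:2 * k + 2, 2 * k:2 * k + 2] = \
                Tk @ C[2 * (k - 1):2 * k, 2 * (k - 1):2 * k] @ Tk.T + Q[k - 1]
        H = np.zeros((n, 2 * n))
        H[np.arange(n), 2 * np.arange(n)] = 1.0
        gains = C @ H.T @ np.linalg.inv(H @ C @ H.T + np.diag(r))
        for axis in range(2):
            post = M[:, axis] + gains @ (y[:, axis] - H @ M[:, axis])
            assert np.max(np.abs(post[0::2] - pos[:, axis])) < 1e-8

    def test_smoother_variance_grows_in_data_gap(self):
        t = pd.to_datetime(
            [f"2019-01-01T{h:02d}:00:00" for h in range(10)]
            + ["2019-01-02T10:00:00", "2019-01-02T11:00:00",
               "2019-01-02T12:00:00"])
        n = len(t)
        df = locs_frame(t, 8 + 0.01 * np.arange(n), [3.0] * n, ["1"] * n)
        tr = regularize(df, "4h")
        assert np.all(tr.sd_km >= 0)
        assert tr.sd_km[len(tr.sd_km) // 2] > tr.sd_km[0]

    def test_short_track_errors(self):
        t = pd.date_range("2019-01-01", periods=5, freq="10min")
        df = locs_frame(t, [8] * 5, [3] * 5, ["3"] * 5)
        with pytest.raises(ValueError):
            regularize(df, "4h")

    def test_smoothing_beats_raw_argos_error(self, island):
        cfg = syn.SimConfig(seed=12)
        tr = syn.simulate_animal(cfg, island, 0)
        obs = syn.observe_argos(tr, cfg)
        f = apply_filters(obs, FilterConfig(),
                          island.by_kind("land")[0].geometry)
        track = regularize(f, "4h")
        tsec = (tr.times - tr.times[0]).total_seconds().to_numpy()

        def errs(times, lon, lat):
            s = (pd.DatetimeIndex(times) - tr.times[0]).total_seconds()
            return haversine_km(np.interp(s, tsec, tr.lon),
                                np.interp(s, tsec, tr.lat), lon, lat)

        raw = errs(obs["timestamp"], obs["lon"].to_numpy(),
                   obs["lat"].to_numpy())
        reg = errs(track.times, track.lon, track.lat)
        assert np.median(reg) < np.median(raw)
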