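import numpy as np
import pandas as pd
import pytest

from nesttrack import nesting
from nesttrack import synthetic as syn
from nesttrack.nesting import (NestingConfig, classify_attempts, cohort_stats,
                               confirm_on_land, detect_attempts,
                               emergence_intervals, nesting_summary, whole_days)


def timeline(values, start="2019-01-01", animal_id="t1", hours=None):
    if hours is None:
        hours = pd.date_range(start, periods=len(values), freq="h", tz="UTC")
    return pd.DataFrame({"animal_id": animal_id, "hour_start": hours,
                         "pct_dry": np.asarray(values, dtype=float)})


def event_at(days, animal_id="t1", n_hours=2):
    t0 = pd.Timestamp("2019-01-01", tz="UTC")
    h0 = t0 + pd.Timedelta(days=days)
    return nesting.NestingEvent(
        animal_id=animal_id,
        event_time=h0 + pd.Timedelta(hours=n_hours / 2),
        peak_hours=[h0 + pd.Timedelta(hours=i) for i in range(n_hours)])


class TestDetect:
    def test_two_hour_run_is_one_candidate(self):
        ev = detect_attempts(timeline([0, 0, 70, 65, 0]), NestingConfig())
        assert len(ev) == 1
        assert len(ev[0].peak_hours) == 2
        assert ev[0].event_time == pd.Timestamp("2019-01-01 03:00", tz="UTC")

    def test_no_candidates_at_or_below_threshold(self):
        ev = detect_attempts(timeline([10, 60.0, 59.9, 0]), NestingConfig())
        assert ev == []         # threshold is strict: 60.0 is not a peak

    def test_missing_hour_breaks_a_run(self):
        hours = pd.DatetimeIndex([
            "2019-01-01 00:00", "2019-01-01 01:00", "2019-01-01 03:00",
        ], tz="UTC")
        ev = detect_attempts(timeline([70, 70, 70], hours=hours),
                             NestingConfig())
        assert len(ev) == 2

    def test_raising_threshold_never_adds_candidates(self, island):
        # holds for the unimodal peak runs that beach emergences produce
        cfg = syn.SimConfig(seed=19)
        tr = syn.simulate_animal(cfg, island, 0)
        dry = syn.observe_drytime(tr, cfg)
        counts = [len(detect_attempts(dry, NestingConfig(dry_threshold=t)))
                  for t in (30, 45, 60, 75, 90)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[2] >= 1

    def test_long_run_flagged_anomalous(self):
        ev = detect_attempts(timeline([70, 70, 70, 70, 70]), NestingConfig())
        assert len(ev) == 1 and ev[0].anomalous


class TestConfirm:
    def _raw(self, times, lons, lats, classes):
        return pd.DataFrame({"animal_id": "t1",
                             "timestamp": pd.DatetimeIndex(times, tz="UTC"),
                             "lon": lons, "lat": lats, "loc_class": classes})

    def test_beach_fix_within_window_confirms(self, island):
        land = island.by_kind("land")[0].geometry
        beach = island.by_kind("beach")[0].geometry
        c = beach.centroid
        ev = event_at(0.0)
        raw = self._raw([ev.event_time + pd.Timedelta("30min")], [c.x], [c.y],
                        ["3"])
        out = confirm_on_land([ev], raw, land, beach, NestingConfig())
        assert out[0].confirmed_on_land is True

    def test_no_fixes_in_window_unconfirmed_but_retained(self, island):
        land = island.by_kind("land")[0].geometry
        beach = island.by_kind("beach")[0].geometry
        ev = event_at(0.0)
        raw = self._raw([ev.event_time + pd.Timedelta("6h")], [0.0], [0.0],
                        ["3"])
        out = confirm_on_land([ev], raw, land, beach, NestingConfig())
        assert out[0].confirmed_on_land is False
        assert len(out) == 1

    def test_class_z_fix_confirms_because_dataset_is_unfiltered(self, island):
        land = island.by_kind("land")[0].geometry
        beach = island.by_kind("beach")[0].geometry
        c = beach.centroid
        ev = event_at(0.0)
        raw = self._raw([ev.event_time], [c.x], [c.y], ["Z"])
        out = confirm_on_land([ev], raw, land, beach, NestingConfig())
        assert out[0].confirmed_on_land is True


class TestClassify:
    def test_pair_within_window_earlier_fails(self):
        ev = classify_attempts([event_at(0), event_at(5)], NestingConfig())
        assert [e.status for e in ev] == ["failed", "successful"]

    def test_well_spaced_events_all_successful(self):
        ev = classify_attempts([event_at(0), event_at(11.5), event_at(23)],
                               NestingConfig())
        assert [e.status for e in ev] == ["successful"] * 3

    def test_chained_window_forward_sweep(self):
        ev = classify_attempts([event_at(0), event_at(5), event_at(12)],
                               NestingConfig())
        assert [e.status for e in ev] == ["failed", "failed", "successful"]

    def test_flanking_zero_single_hour_peak_fails(self):
        tl = timeline([0, 75, 0])
        ev = detect_attempts(tl, NestingConfig())
        out = classify_attempts(ev, NestingConfig(), tl)
        assert out[0].status == "failed"

    def test_missing_flanking_record_leaves_rule_inapplicable(self):
        hours = pd.DatetimeIndex(["2019-01-01 00:00", "2019-01-01 01:00"],
                                 tz="UTC")
        tl = timeline([0, 75], hours=hours)   # hour after the peak is absent
        ev = detect_attempts(tl, NestingConfig())
        out = classify_attempts(ev, NestingConfig(), tl)
        assert out[0].status == "successful"

    def test_every_event_gets_exactly_one_status(self):
        rng = np.random.default_rng(2)
        days = np.cumsum(rng.uniform(2, 14, 12))
        ev = classify_attempts([event_at(d) for d in days], NestingConfig())
        assert all(e.status in ("successful", "failed") for e in ev)


class TestSummary:
    def test_intervals_between_successful_events(self):
        ev = classify_attempts([event_at(0), event_at(11), event_at(23)],
                               NestingConfig())
        s = nesting_summary(ev, pd.Timestamp("2019-01-01", tz="UTC"),
                            pd.Timestamp("2019-01-25", tz="UTC"))
        assert s["intervals_days"] == pytest.approx([11.0, 12.0])
        assert s["successful_clutches"] == 3

    def test_immediate_migrant_zero_duration(self):
        t = pd.Timestamp("2019-01-13", tz="UTC")
        s = nesting_summary([event_at(0)], t, t)
        assert s["observed_nesting_duration_days"] == 0

    def test_whole_day_convention(self):
        assert whole_days("2019-01-12", "2019-02-05") == 24
        assert whole_days("2019-02-05T23:00", "2019-02-06T01:00") == 1

    def test_cohort_stats_sample_sd(self):
        m, s = cohort_stats([1.0, 2.0, 3.0, None])
        assert m == 2.0 and s == pytest.approx(1.0)


class TestRecallPrecision:
    def test_detection_recall_and_precision_on_default_cohort(self, island):
        cfg = syn.SimConfig(seed=21)
        ncfg = NestingConfig()
        tp = fn = fp = 0
        for i in range(10):
            tr = syn.simulate_animal(cfg, island, i)
            dry = syn.observe_drytime(tr, cfg)
            ev = detect_attempts(dry, ncfg)
            det = sorted(e.event_time for e in ev)
            used = set()
            for s, e, _o in tr.nesting_events:
                mid = s + (e - s) / 2
                hit = [j for j, t in enumerate(det)
                       if j not in used
                       and abs((t - mid).total_seconds()) < 2.5 * 3600]
                if hit:
                    used.add(hit[0])
                    tp += 1
                else:
                    fn += 1
            fp += len(det) - len(used)
        recall = tp / (tp + fn)
        precision = tp / (tp + fp)
        assert recall >= 0.9
        assert precision >= 0.9

    def test_emergence_interval_estimator_tracks_schedule(self, island):
        cfg = syn.SimConfig(seed=31)
        gaps = []
        for i in range(6):
            tr = syn.simulate_animal(cfg, island, i)
            dry = syn.observe_drytime(tr, cfg)
            ev = detect_attempts(dry, NestingConfig())
            gaps.extend(emergence_intervals(ev))
        assert len(gaps) > 5
        assert np.mean(gaps) == pytest.approx(cfg.nesting_interval_mean, abs=1.0)
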