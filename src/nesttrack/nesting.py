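"""Nesting-event detection from hourly dry-time timelines.

A beach emergence keeps the tag's wet/dry sensor dry for most of an hour,
so nesting attempts appear as runs of hours with percent-dry above a
threshold (default 60 %, i.e. at least 36 dry minutes in an hour for an
event spread over two consecutive hours).  Candidates are confirmed against
the *unfiltered* Argos fixes near the event time, then classified:

* a single-hour peak flanked by recorded 0 % hours is a likely failed
  attempt (too brief to have been a nesting);
* of two or more attempts closer together than the re-nesting window
  (default 10 d), only the latest is a likely successful nesting — resolved
  by a forward sweep so chains (days 0, 5, 12) fail all but the last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely import contains_xy

from ._geo import LocalEquirect, project_geometry

HOUR = pd.Timedelta(hours=1)


@dataclass
class NestingConfig:
    dry_threshold: float = 60.0      # percent, strict >
    renest_window: float = 10.0      # days
    confirm_window: float = 1.0      # hours each side of the event time
    confirm_radius: float = 2.0      # km from the beach for on-land check
    anomalous_run_hours: int = 3     # longer runs flagged (nesting <= 187 min)

    def __post_init__(self):
        if not 0 < self.dry_threshold < 100:
            raise ValueError("dry_threshold must be in (0, 100)")
        if self.renest_window <= 0:
            raise ValueError("renest_window must be > 0")


@dataclass
class NestingEvent:
    animal_id: str
    event_time: pd.Timestamp         # centre of the peak run
    peak_hours: list                 # contiguous hour_start timestamps
    status: str | None = None        # "successful" | "failed"
    confirmed_on_land: bool | None = None
    anomalous: bool = field(default=False)


def detect_attempts(timeline: pd.DataFrame, cfg: NestingConfig) -> list:
    """Maximal runs of consecutive hours with pct_dry strictly above the
    threshold, one candidate per run; event time is the run midpoint.
    A missing hour record breaks a run."""
    if len(timeline) == 0:
        raise ValueError("empty dry-time timeline")
    tl = timeline.sort_values("hour_start")
    animal_id = str(tl["animal_id"].iloc[0])
    hours = pd.DatetimeIndex(tl["hour_start"])
    hot = tl["pct_dry"].to_numpy(float) > cfg.dry_threshold
    events = []
    run: list = []
    prev = None
    for h, flag in zip(hours, hot):
        contiguous = prev is not None and (h - prev) == HOUR
        if flag and run and contiguous:
            run.append(h)
        elif flag:
            if run:
                events.append(run)
            run = [h]
        else:
            if run:
                events.append(run)
            run = []
        prev = h
    if run:
        events.append(run)
    out = []
    for run in events:
        mid = run[0] + HOUR * len(run) / 2
        out.append(NestingEvent(animal_id=animal_id, event_time=mid,
                                peak_hours=list(run),
                                anomalous=len(run) > cfg.anomalous_run_hours))
    return out


def confirm_on_land(candidates: list, raw_locs: pd.DataFrame, land_geometry,
                    beach_geometry, cfg: NestingConfig) -> list:
    """Set ``confirmed_on_land`` from the pre-filter Argos fixes.

    A candidate is confirmed if any raw fix (any location class, including
    those the track filters would drop) within +/- ``confirm_window`` hours
    of the event time lies on land or within ``confirm_radius`` km of the
    beach.  Unconfirmed candidates are retained, only flagged.
    """
    c = beach_geometry.centroid
    proj = LocalEquirect(c.x, c.y)
    beach_km = project_geometry(beach_geometry, proj)
    ts = pd.DatetimeIndex(raw_locs["timestamp"])
    lon = raw_locs["lon"].to_numpy(float)
    lat = raw_locs["lat"].to_numpy(float)
    w = pd.Timedelta(hours=cfg.confirm_window)
    for ev in candidates:
        m = np.asarray((ts >= ev.event_time - w) & (ts <= ev.event_time + w))
        if not m.any():
            ev.confirmed_on_land = False
            continue
        on_land = contains_xy(land_geometry, lon[m], lat[m])
        if on_land.any():
            ev.confirmed_on_land = True
            continue
        x, y = proj.forward(lon[m], lat[m])
        pts = shapely.points(np.atleast_1d(x), np.atleast_1d(y))
        dists = shapely.distance(beach_km, pts)
        ev.confirmed_on_land = bool(np.min(dists) <= cfg.confirm_radius)
    return candidates


def classify_attempts(events: list, cfg: NestingConfig,
                      timeline: pd.DataFrame | None = None) -> list:
    """Assign a terminal status to every candidate.

    Rule 1 (flanking zeros): a single-hour peak whose adjacent hours are
    both *recorded* as exactly 0 % dry is a failed attempt; a missing hour
    record leaves the rule inapplicable.  Rule 2 (re-nesting window,
    forward sweep): among events not already failed, the earlier of any
    pair closer than the window fails.  Survivors are successful.
    """
    events = sorted(events, key=lambda e: e.event_time)
    lookup = {}
    if timeline is not None:
        tl = timeline.sort_values("hour_start")
        lookup = dict(zip(pd.DatetimeIndex(tl["hour_start"]),
                          tl["pct_dry"].to_numpy(float)))
    for ev in events:
        if len(ev.peak_hours) == 1 and lookup:
            h = ev.peak_hours[0]
            before = lookup.get(h - HOUR)
            after = lookup.get(h + HOUR)
            if before == 0.0 and after == 0.0:
                ev.status = "failed"
    window = pd.Timedelta(days=cfg.renest_window)
    prev = None
    for ev in events:
        if ev.status == "failed":
            continue
        if prev is not None and (ev.event_time - prev.event_time) < window:
            prev.status = "failed"
        prev = ev
    for ev in events:
        if ev.status is None:
            ev.status = "successful"
    return events


def emergence_intervals(events: list) -> np.ndarray:
    """Gaps in days between consecutive detected emergences (any status).

    This is the estimator of the beach-return interval: the re-nesting
    window rule censors sub-window gaps between *successful* events by
    construction, so gaps over all detected emergences are the unbiased
    measure of the return clock.
    """
    t = sorted(e.event_time for e in events)
    if len(t) < 2:
        return np.array([])
    return np.diff(pd.DatetimeIndex(t).asi8) / 86400e9


def successful_intervals(events: list) -> np.ndarray:
    """Gaps in days between consecutive successful events."""
    t = sorted(e.event_time for e in events if e.status == "successful")
    if len(t) < 2:
        return np.array([])
    return np.diff(pd.DatetimeIndex(t).asi8) / 86400e9


def whole_days(start, end) -> int:
    """Calendar-day difference (end date minus start date)."""
    return (pd.Timestamp(end).normalize() - pd.Timestamp(start).normalize()).days


def nesting_summary(events: list, tagging_time, migration_start) -> dict:
    """Per-animal summary: attempt/success counts, inter-nesting intervals
    and the observed nesting duration in whole days (tagging to migration
    onset; 0 for an immediate migrant)."""
    succ = [e for e in events if e.status == "successful"]
    duration = (whole_days(tagging_time, migration_start)
                if migration_start is not None else None)
    return {
        "attempts": len(events),
        "successful_clutches": len(succ),
        "intervals_days": successful_intervals(events).tolist(),
        "emergence_intervals_days": emergence_intervals(events).tolist(),
        "observed_nesting_duration_days": duration,
    }


def cohort_stats(values) -> tuple:
    """(mean, sample sd) with n-1 in the denominator."""
    v = np.asarray([x for x in values if x is not None], dtype=float)
    if len(v) == 0:
        return np.nan, np.nan
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
    return float(np.mean(v)), sd
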