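"""Ground-truthed synthetic datasets for a nesting sea-turtle tracking study.

The generator emulates the statistical structure of a satellite-tagging
campaign on a small volcanic island rookery: a stylized island with a 3-km
nesting beach inside a partly-marine scientific reserve, females that loop
offshore (up to ~108 km) between beach emergences spaced ~11.5 d apart,
on-land nesting events of 72-187 min, Argos-quality location errors by
class, hourly wet/dry sensor timelines, a directed post-nesting migration
followed by area-restricted movement, and monthly gridded fishing effort.

Every stochastic output is reproducible from (seed, animal_index).  True
paths are simulated at 10-min resolution in a local tangent plane near the
island (error < 0.5 % within 500 km) and by spherical dead-reckoning during
the long migration leg.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon, box

from ._geo import LocalEquirect, destination, project_geometry
from .io_formats import ARGOS_CLASSES, EffortGrid, NamedRegionSet

_DEF_CLASS_PROBS = {"3": 0.08, "2": 0.12, "1": 0.15, "0": 0.10,
                    "A": 0.25, "B": 0.28, "Z": 0.02}
# Per-class isotropic error sd (km).  Only the endpoints (~0.4 km for LC 3,
# > 10 km for the worst classes) are pinned by the Argos literature; the
# middle classes interpolate standard values and are configurable.
_DEF_ERROR_SD = {"3": 0.4, "2": 1.0, "1": 1.5, "A": 4.0,
                 "B": 10.0, "0": 10.0, "Z": 14.0}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults encode the field numbers the analysis assumes: beach returns at
    Normal(11.5, 1.8) day intervals truncated at >= 8 d, 1-4 successful
    clutches, on-land nesting events of 72-187 min, offshore loop extent up
    to 108 km, and Argos class error from 0.4 km (LC 3) upward.
    """

    n_animals: int = 10
    nesting_interval_mean: float = 11.5   # days
    nesting_interval_sd: float = 1.8      # days
    nesting_interval_min: float = 8.0     # truncation, days
    n_clutches_range: tuple = (1, 4)      # successful clutches, inclusive
    nesting_duration_range: tuple = (72.0, 187.0)   # minutes, successful
    failed_fraction: float = 0.3          # probability a post-tagging visit fails
    failed_spike_fraction: float = 0.8    # of failed visits: single-hour dry spike
    failed_spike_duration_range: tuple = (40.0, 58.0)    # minutes
    failed_straddle_duration_range: tuple = (62.0, 71.0)  # minutes
    internesting_trip_max_km: float = 108.0
    internesting_trip_min_km: float = 20.0
    migration_group_probs: dict = field(
        default_factory=lambda: {"central_atlantic": 0.7, "south_america": 0.3})
    migration_speed: float = 45.0         # km/day, directed phase
    ars_speed: float = 15.0               # km/day, area-restricted phase
    directed_days_range: dict = field(
        default_factory=lambda: {"central_atlantic": (40.0, 60.0),
                                 "south_america": (80.0, 110.0)})
    ars_days: float = 30.0
    argos_class_probs: dict = field(default_factory=lambda: dict(_DEF_CLASS_PROBS))
    argos_error_sd_km: dict = field(default_factory=lambda: dict(_DEF_ERROR_SD))
    fix_rate_per_day: float = 8.0
    drytime_background_max: float = 20.0  # percent of an at-sea hour
    drytime_background_zero_prob: float = 0.5
    step_minutes: float = 10.0
    tagging_date: str = "2019-01-14T22:00:00Z"
    seed: int = 0

    def __post_init__(self):
        p = sum(self.migration_group_probs.values())
        if abs(p - 1.0) > 1e-9:
            raise ValueError("migration_group_probs must sum to 1")
        p = sum(self.argos_class_probs.values())
        if abs(p - 1.0) > 1e-9:
            raise ValueError("argos_class_probs must sum to 1")
        for v in (self.nesting_interval_mean, self.nesting_interval_sd,
                  self.internesting_trip_max_km, self.migration_speed,
                  self.ars_speed, self.fix_rate_per_day):
            if v <= 0:
                raise ValueError("all scale parameters must be > 0")
        b = self.argos_error_sd_km.get("B", 0.0)
        for c in ("0", "Z"):
            if self.argos_error_sd_km.get(c, b) < b:
                raise ValueError(f"class {c} error sd must be >= class B's")


@dataclass
class TruthRecord:
    """Ground truth for one simulated animal."""

    animal_id: str
    times: pd.DatetimeIndex          # 10-min grid, UTC
    lon: np.ndarray
    lat: np.ndarray
    on_land: np.ndarray              # bool per grid point
    nesting_events: list             # (start, end, outcome) with outcome in
                                     # {"successful", "failed"}
    migration_start: pd.Timestamp
    migration_group: str
    tagging_time: pd.Timestamp
    origin: tuple                    # (lon, lat) of the tagging beach position


# ---------------------------------------------------------------------------
# Region construction


def make_island(center_lon: float = 8.70, center_lat: float = 3.40,
                island_radius_km: float = 12.0, beach_length_km: float = 3.0,
                reserve_marine_breadth_km: float = 2.0,
                reserve_arc_deg: float = 60.0) -> NamedRegionSet:
    """Build the stylized study-region polygon set.

    Returns land (circular island), a 3-km beach arc on the south coast, a
    scientific reserve spanning ``reserve_arc_deg`` of the southern sector
    whose marine part extends ``reserve_marine_breadth_km`` offshore, two
    abutting EEZ rectangles, and implicitly the surrounding high seas
    (anything outside every EEZ).
    """
    proj = LocalEquirect(center_lon, center_lat)
    R = island_radius_km

    def ring(radius, az0=-180.0, az1=180.0, n=257):
        az = np.radians(np.linspace(az0, az1, n))
        # azimuth measured clockwise from south (0 = due south of centre)
        return np.column_stack([radius * np.sin(az), -radius * np.cos(az)])

    land_xy = Polygon(ring(R))
    half_arc = np.degrees(0.5 * beach_length_km / R)
    beach_line = ring(R, -half_arc, half_arc, 33)
    beach_xy = Polygon(np.vstack([
        beach_line * ((R + 0.3) / R),
        beach_line[::-1] * ((R - 0.3) / R),
    ]))
    half_res = reserve_arc_deg / 2.0
    outer = ring(R + reserve_marine_breadth_km, -half_res, half_res, 65)
    inner = ring(max(R - 7.0, 1.0), -half_res, half_res, 65)
    reserve_xy = Polygon(np.vstack([outer, inner[::-1]]))

    regions = NamedRegionSet()
    regions.add("bioko_island", "land", project_geometry(land_xy, proj, "inverse"))
    regions.add("moaba_beach", "beach", project_geometry(beach_xy, proj, "inverse"))
    regions.add("luba_reserve", "reserve",
                project_geometry(reserve_xy, proj, "inverse"))
    # Abutting EEZ rectangles in lon/lat; first-declared wins boundary ties.
    regions.add("equatorial_guinea", "eez", box(7.2, 1.6, 10.2, 5.2))
    regions.add("sao_tome_principe", "eez", box(4.8, -0.5, 7.2, 2.5))
    return regions


def _beach_frame(regions: NamedRegionSet):
    """Projection centred on the beach plus the beach anchor in plane km."""
    beach = [r for r in regions.regions if r.kind == "beach"]
    if not beach:
        raise ValueError("configuration error: no 'beach' region in region set")
    land = regions.by_kind("land")
    if not land:
        raise ValueError("configuration error: no 'land' region in region set")
    c = land[0].geometry.centroid
    proj = LocalEquirect(c.x, c.y)
    bc = beach[0].geometry.centroid
    bx, by = proj.forward(bc.x, bc.y)
    # outward normal of the coast at the beach (away from the island centre)
    nrm = np.array([bx, by])
    nrm = nrm / max(np.hypot(*nrm), 1e-9)
    return proj, np.array([bx, by]), nrm


# ---------------------------------------------------------------------------
# Animal simulation


def _truncnorm_days(rng, mean, sd, lo):
    a = (lo - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                     random_state=rng))


def _snap_into_hour(start: pd.Timestamp, duration_min: float) -> pd.Timestamp:
    """Shift a start time so [start, start+duration] sits inside one clock hour."""
    top = start.floor("h")
    offset = (start - top).total_seconds() / 60.0
    latest = 60.0 - duration_min
    if latest < 0:
        return start
    return top + pd.Timedelta(minutes=min(offset, latest))


def _schedule_visits(cfg: SimConfig, rng) -> tuple:
    """Beach-emergence schedule: (list of (start, end, outcome), migration_start).

    The first emergence is the tagging night and is always a successful
    clutch; subsequent returns follow the truncated-normal interval clock
    until the drawn number of successful clutches is reached, each return
    failing with probability ``failed_fraction``.
    """
    t0 = pd.Timestamp(cfg.tagging_date)
    n_success = int(rng.integers(cfg.n_clutches_range[0],
                                 cfg.n_clutches_range[1] + 1))
    events = []
    d0 = float(rng.uniform(*cfg.nesting_duration_range))
    events.append((t0, t0 + pd.Timedelta(minutes=d0), "successful"))
    successes = 1
    t = t0
    while successes < n_success:
        gap = _truncnorm_days(rng, cfg.nesting_interval_mean,
                              cfg.nesting_interval_sd, cfg.nesting_interval_min)
        t = t + pd.Timedelta(days=gap)
        if rng.uniform() < cfg.failed_fraction:
            if rng.uniform() < cfg.failed_spike_fraction:
                dur = float(rng.uniform(*cfg.failed_spike_duration_range))
                start = _snap_into_hour(t, dur)
            else:
                dur = float(rng.uniform(*cfg.failed_straddle_duration_range))
                start = t
            events.append((start, start + pd.Timedelta(minutes=dur), "failed"))
        else:
            dur = float(rng.uniform(*cfg.nesting_duration_range))
            events.append((t, t + pd.Timedelta(minutes=dur), "successful"))
            successes += 1
    migration_start = events[-1][1]
    return events, migration_start


def _loop_xy(rng, cfg: SimConfig, p_from, p_to, seaward, n_steps):
    """Offshore out-and-back loop between two beach exits, in plane km."""
    u = np.linspace(0.0, 1.0, n_steps)
    L = rng.uniform(cfg.internesting_trip_min_km,
                    cfg.internesting_trip_max_km)
    base_phi = np.arctan2(seaward[1], seaward[0])
    phi0 = base_phi + np.radians(rng.uniform(-55.0, 55.0))
    drift = np.radians(rng.uniform(-40.0, 40.0))
    phi = phi0 + (u - 0.5) * drift
    r = L * np.sin(np.pi * u)
    anchor = np.outer(1.0 - u, p_from) + np.outer(u, p_to)
    path = anchor + np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    # Brownian-bridge wiggle so the loop is not perfectly smooth
    w = np.cumsum(rng.normal(0.0, 0.08, size=(n_steps, 2)), axis=0)
    w -= np.outer(u, w[-1])
    return path + w


def simulate_animal(cfg: SimConfig, regions: NamedRegionSet,
                    animal_index: int) -> TruthRecord:
    """Simulate one animal's true 10-min path and ground-truth events.

    Deterministic in (cfg.seed, animal_index).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, animal_index]))
    proj, beach_xy, seaward = _beach_frame(regions)
    events, migration_start = _schedule_visits(cfg, rng)

    step = pd.Timedelta(minutes=cfg.step_minutes)
    group = str(rng.choice(list(cfg.migration_group_probs.keys()),
                           p=list(cfg.migration_group_probs.values())))
    directed_days = float(rng.uniform(*cfg.directed_days_range[group]))
    t0 = events[0][0]
    t_end = migration_start + pd.Timedelta(days=directed_days + cfg.ars_days)
    times = pd.date_range(t0, t_end, freq=step)
    n = len(times)
    xy = np.zeros((n, 2))
    on_land = np.zeros(n, dtype=bool)

    # per-event nest position: on the beach, slightly inland, spread alongshore
    along = np.array([-seaward[1], seaward[0]])
    nest_pts = []
    for _ in events:
        s = rng.uniform(-1.4, 1.4)
        nest_pts.append(beach_xy + along * s - seaward * 0.1)
    exit_pts = [p + seaward * 0.4 for p in nest_pts]

    tsec = (times - t0).total_seconds().to_numpy()

    def idx(ts):
        return int(np.searchsorted(tsec, (ts - t0).total_seconds()))

    # inter-nesting: visits (stationary, on land) and loops between them
    for k, (es, ee, _outcome) in enumerate(events):
        i0, i1 = idx(es), idx(ee)
        xy[i0:i1 + 1] = nest_pts[k]
        on_land[i0:i1 + 1] = True
        if k + 1 < len(events):
            j0, j1 = i1 + 1, idx(events[k + 1][0]) - 1
            if j1 >= j0:
                xy[j0:j1 + 1] = _loop_xy(rng, cfg, exit_pts[k], exit_pts[k + 1],
                                         seaward, j1 - j0 + 1)

    lon = np.empty(n)
    lat = np.empty(n)
    im = idx(migration_start)
    lon[:im + 1], lat[:im + 1] = proj.inverse(xy[:im + 1, 0], xy[:im + 1, 1])

    # migration: spherical dead-reckoning at fixed group heading, then ARS
    heading = {"central_atlantic": 235.0, "south_america": 240.0}.get(group, 235.0)
    dt_days = cfg.step_minutes / 1440.0
    n_mig = n - im - 1
    if n_mig > 0:
        n_dir = min(n_mig, int(round(directed_days / dt_days)))
        brg = np.empty(n_mig)
        spd = np.empty(n_mig)
        b = heading + rng.normal(0, 3)
        for i in range(n_mig):
            if i < n_dir:
                b = b + rng.normal(0.0, 1.5)
                b = heading + 0.8 * (b - heading)   # mean-reverting heading
                brg[i] = b
                spd[i] = cfg.migration_speed * max(0.2, 1 + 0.2 * rng.normal())
            else:
                brg[i] = brg[i - 1] + rng.normal(0.0, 35.0) if i else heading
                spd[i] = cfg.ars_speed * max(0.1, 1 + 0.3 * rng.normal())
        lo, la = lon[im], lat[im]
        for i in range(n_mig):
            lo, la = destination(lo, la, brg[i], spd[i] * dt_days)
            lon[im + 1 + i], lat[im + 1 + i] = lo, la

    return TruthRecord(
        animal_id=f"turtle_{animal_index + 1:02d}",
        times=times, lon=lon, lat=lat, on_land=on_land,
        nesting_events=[(pd.Timestamp(s), pd.Timestamp(e), o)
                        for s, e, o in events],
        migration_start=pd.Timestamp(migration_start),
        migration_group=group,
        tagging_time=pd.Timestamp(t0),
        origin=(float(lon[0]), float(lat[0])),
    )


# ---------------------------------------------------------------------------
# Observation models


def observe_argos(truth: TruthRecord, cfg: SimConfig,
                  rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Argos-like fixes along the true path.

    Fix times follow a Poisson process at ``fix_rate_per_day``; each fix
    draws a location class and an isotropic Gaussian position error with the
    class's sd (km).  Returns a location table like ``read_argos_csv``'s.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(
            [cfg.seed, 7_000_001, zlib.crc32(truth.animal_id.encode())]))
    span_s = (truth.times[-1] - truth.times[0]).total_seconds()
    rate_s = cfg.fix_rate_per_day / 86400.0
    gaps = rng.exponential(1.0 / rate_s, size=int(rate_s * span_s * 1.5) + 20)
    t_off = np.cumsum(np.maximum(gaps, 1.0))
    t_off = t_off[t_off < span_s]
    tsec = (truth.times - truth.times[0]).total_seconds().to_numpy()
    flon = np.interp(t_off, tsec, truth.lon)
    flat = np.interp(t_off, tsec, truth.lat)
    classes = rng.choice(list(cfg.argos_class_probs.keys()), size=len(t_off),
                         p=list(cfg.argos_class_probs.values()))
    sds = np.array([cfg.argos_error_sd_km[c] for c in classes])
    dx = rng.normal(0.0, 1.0, len(t_off)) * sds
    dy = rng.normal(0.0, 1.0, len(t_off)) * sds
    dist = np.hypot(dx, dy)
    brg = np.degrees(np.arctan2(dx, dy))   # bearing clockwise from north
    olon, olat = destination(flon, flat, brg, dist)
    ts = truth.times[0] + pd.to_timedelta(np.round(t_off), unit="s")
    return pd.DataFrame({
        "animal_id": truth.animal_id,
        "timestamp": ts,
        "lon": olon,
        "lat": olat,
        "loc_class": classes,
    })


def observe_drytime(truth: TruthRecord, cfg: SimConfig,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Hourly percent-dry timeline implied by the truth record.

    Each hour's value is (minutes on land within the hour, by exact overlap
    with the nesting events) plus a small surfacing background (<= 20 % of
    the at-sea portion of the hour, zero for about half the hours).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(
            [cfg.seed, 7_000_002, zlib.crc32(truth.animal_id.encode())]))
    h0 = truth.times[0].floor("h")
    h1 = truth.times[-1].ceil("h")
    hours = pd.date_range(h0, h1 - pd.Timedelta(hours=1), freq="h")
    land_min = np.zeros(len(hours))
    hs = hours.asi8 / 1e9
    for (es, ee, _o) in truth.nesting_events:
        s, e = es.value / 1e9, ee.value / 1e9
        ov = np.minimum(hs + 3600.0, e) - np.maximum(hs, s)
        land_min += np.maximum(ov, 0.0) / 60.0
    land_min = np.minimum(land_min, 60.0)
    zero = rng.uniform(size=len(hours)) < cfg.drytime_background_zero_prob
    bg_frac = np.where(zero, 0.0,
                       rng.uniform(0.0, cfg.drytime_background_max / 100.0,
                                   len(hours)))
    pct = 100.0 * land_min / 60.0 + 100.0 * bg_frac * (60.0 - land_min) / 60.0
    return pd.DataFrame({
        "animal_id": truth.animal_id,
        "hour_start": hours,
        "pct_dry": np.clip(pct, 0.0, 100.0),
    })


# ---------------------------------------------------------------------------
# Fishing effort


def simulate_effort(regions: NamedRegionSet, cfg: SimConfig, seed: int,
                    years=(2018, 2019), months=range(2, 9),
                    cells_per_gear: int = 250, cell_size: float = 0.1,
                    bbox=(-40.0, -22.0, 11.0, 7.0),
                    intensity: float = 1.0) -> EffortGrid:
    """Monthly 0.1-degree effort grids for longline and purse-seine fleets.

    Longline effort concentrates in high-seas cells, purse-seine effort in
    EEZ cells, mirroring the contrast the analysis expects.  ``intensity``
    scales mean hours; zero yields an empty grid.  Deterministic in seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9_000_001]))
    lon0, lat0, lon1, lat1 = bbox
    eezs = [r.geometry for r in regions.by_kind("eez")]
    rows = []
    if intensity <= 0:
        return EffortGrid(cell_size=cell_size,
                          cells=pd.DataFrame(columns=["lat", "lon", "gear",
                                                      "month", "hours"]))

    def sample_cells(gear, n):
        p_eez = 0.85 if gear == "purse_seine" else 0.10
        out = []
        for _ in range(n):
            want_eez = rng.uniform() < p_eez
            for _try in range(500):
                lo = np.floor(rng.uniform(lon0, lon1) / cell_size) * cell_size
                la = np.floor(rng.uniform(lat0, lat1) / cell_size) * cell_size
                p = Point(lo + cell_size / 2, la + cell_size / 2)
                if any(g.contains(p) for g in eezs) == want_eez:
                    out.append((round(lo, 6), round(la, 6)))
                    break
        return out

    for gear in ("longline", "purse_seine"):
        cells = sample_cells(gear, cells_per_gear)
        for year in years:
            for month in months:
                hours = rng.gamma(2.0, 8.0 * intensity, size=len(cells))
                for (lo, la), h in zip(cells, hours):
                    rows.append((la, lo, gear, f"{year}-{month:02d}", float(h)))
    df = pd.DataFrame(rows, columns=["lat", "lon", "gear", "month", "hours"])
    return EffortGrid(cell_size=cell_size, cells=df)


# ---------------------------------------------------------------------------
# Cohort convenience


def simulate_cohort(cfg: SimConfig, regions: Optional[NamedRegionSet] = None):
    """Simulate the full cohort; returns (regions, truths, argos_df, dry_df)."""
    if regions is None:
        regions = make_island()
    truths, argos, dry = [], [], []
    for i in range(cfg.n_animals):
        tr = simulate_animal(cfg, regions, i)
        truths.append(tr)
        argos.append(observe_argos(tr, cfg))
        dry.append(observe_drytime(tr, cfg))
    return regions, truths, pd.concat(argos, ignore_index=True), \
        pd.concat(dry, ignore_index=True)
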