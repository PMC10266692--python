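"""Post-nesting migration summaries and fishing-effort overlap.

Displacement metrics follow the tagging-report conventions: final
displacement is the great-circle distance from the tagging location to the
last fix, total distance the along-track sum of step distances, and the
migratory group is read off the maximum displacement — transatlantic
dispersers (toward South America) exceed ~3,200 km while residents of the
central Atlantic stay below it; short tracks stay unclassified.

Fishing effort arrives as monthly 0.1-degree grids per gear, is aggregated
to 0.5-degree cells (summing constituent cells, conserving total hours),
then to yearly February-August sums and a long-term per-cell mean.  The
overlap index maps each daily location to its 0.5-degree cell and sums that
cell's long-term effort — an explicit exposure statistic in place of visual
map comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geo import haversine_km
from .io_formats import EffortGrid
from .nesting import whole_days
from .preprocessing import RegularTrack

GROUP_THRESHOLD_KM = 3200.0     # midpoint of the gap between dispersal groups
MIN_CLASSIFIABLE_DAYS = 30.0
MIGRATION_MONTHS = tuple(range(2, 9))   # February-August


@dataclass
class MigrationSummary:
    animal_id: str
    migration_start: pd.Timestamp
    final_displacement_km: float
    max_displacement_km: float
    total_path_km: float
    duration_days: int
    group: str                  # central_atlantic | south_america | unclassified


def classify_group(max_displacement_km: float, duration_days: float,
                   threshold_km: float = GROUP_THRESHOLD_KM,
                   min_days: float = MIN_CLASSIFIABLE_DAYS) -> str:
    if max_displacement_km >= threshold_km:
        return "south_america"
    if duration_days >= min_days:
        return "central_atlantic"
    return "unclassified"


def migration_summary(track: RegularTrack, migration_start,
                      origin: tuple | None = None,
                      threshold_km: float = GROUP_THRESHOLD_KM) -> MigrationSummary:
    """Displacement metrics for a post-nesting daily track.

    ``origin`` defaults to the track's first position; passing the tagging
    location instead measures displacement from the tagging site (both
    conventions are in circulation — be explicit when comparing cohorts).
    """
    if origin is None:
        origin = (float(track.lon[0]), float(track.lat[0]))
    d = haversine_km(origin[0], origin[1], track.lon, track.lat)
    steps = haversine_km(track.lon[:-1], track.lat[:-1],
                         track.lon[1:], track.lat[1:])
    duration = whole_days(migration_start, track.times[-1])
    group = classify_group(float(d.max()) if len(d) else 0.0, duration,
                           threshold_km)
    return MigrationSummary(
        animal_id=track.animal_id,
        migration_start=pd.Timestamp(migration_start),
        final_displacement_km=float(d[-1]) if len(d) else 0.0,
        max_displacement_km=float(d.max()) if len(d) else 0.0,
        total_path_km=float(steps.sum()) if len(steps) else 0.0,
        duration_days=duration,
        group=group,
    )


# ---------------------------------------------------------------------------
# Effort aggregation


def regrid_effort(grid: EffortGrid, target_cell_size: float = 0.5) -> EffortGrid:
    """Sum effort onto a coarser grid; the target must be an integer
    multiple of the source cell size.  Total hours are conserved exactly."""
    ratio = target_cell_size / grid.cell_size
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("target cell size must be an integer multiple of "
                         f"{grid.cell_size}")
    df = grid.cells
    if len(df) == 0:
        return EffortGrid(cell_size=target_cell_size, cells=df.copy())
    out = df.copy()
    out["lat"] = np.floor(np.round(df["lat"] / grid.cell_size)
                          * grid.cell_size / target_cell_size) * target_cell_size
    out["lon"] = np.floor(np.round(df["lon"] / grid.cell_size)
                          * grid.cell_size / target_cell_size) * target_cell_size
    out = (out.groupby(["lat", "lon", "gear", "month"], as_index=False)["hours"]
              .sum())
    return EffortGrid(cell_size=target_cell_size, cells=out)


def longterm_mean(grid: EffortGrid, months=MIGRATION_MONTHS) -> pd.DataFrame:
    """Long-term mean effort per cell and gear over the migration months.

    Yearly cumulative effort is the sum of the selected months within each
    year; the long-term mean averages those yearly sums over the years
    present.  A ``combined`` gear (longline + purse seine) is appended.
    Returns columns ``lat, lon, gear, hours``.
    """
    df = grid.cells
    if len(df) == 0:
        return pd.DataFrame(columns=["lat", "lon", "gear", "hours"])
    per = pd.PeriodIndex(df["month"], freq="M")
    sel = df[np.isin(per.month, list(months))].copy()
    sel["year"] = pd.PeriodIndex(sel["month"], freq="M").year
    n_years = sel["year"].nunique()
    yearly = (sel.groupby(["lat", "lon", "gear", "year"], as_index=False)["hours"]
                 .sum())
    lt = (yearly.groupby(["lat", "lon", "gear"], as_index=False)["hours"]
                .sum())
    lt["hours"] /= max(n_years, 1)      # cells absent in a year count as 0
    combined = (lt.groupby(["lat", "lon"], as_index=False)["hours"].sum())
    combined["gear"] = "combined"
    return pd.concat([lt, combined[["lat", "lon", "gear", "hours"]]],
                     ignore_index=True)


@dataclass
class OverlapSummary:
    animal_id: str
    n_days: int
    exposure_hours: dict        # gear -> summed cell effort over daily fixes
    mean_hours: dict            # gear -> exposure / n_days


def track_effort_overlap(daily_track: RegularTrack, longterm: pd.DataFrame,
                         cell_size: float = 0.5) -> OverlapSummary:
    """Effort-weighted exposure of a daily track.

    Each daily position maps to its half-open lower-left-origin cell
    [lat, lat+s) x [lon, lon+s); exposure per gear is the sum of that
    cell's long-term mean hours over the track's days.
    """
    lat_bin = np.floor(daily_track.lat / cell_size) * cell_size
    lon_bin = np.floor(daily_track.lon / cell_size) * cell_size
    n = len(daily_track.times)
    exposure = {}
    mean = {}
    gears = sorted(longterm["gear"].unique()) if len(longterm) else ["combined"]
    for gear in gears:
        g = longterm[longterm["gear"] == gear]
        lut = {(round(la, 6), round(lo, 6)): h
               for la, lo, h in zip(g["lat"], g["lon"], g["hours"])}
        tot = float(sum(lut.get((round(la, 6), round(lo, 6)), 0.0)
                        for la, lo in zip(lat_bin, lon_bin)))
        exposure[gear] = tot
        mean[gear] = tot / n if n else np.nan
    return OverlapSummary(animal_id=daily_track.animal_id, n_days=n,
                          exposure_hours=exposure, mean_hours=mean)
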