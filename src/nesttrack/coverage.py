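"""Protected-area coverage and EEZ residency.

Because tracks are regularized to a uniform interval, the share of grid
points inside a polygon measures the share of *time* spent there.  Reserve
expansion scenarios are ring buffers of the coastline segment adjacent to
the reserve's sea-facing boundary, grown seaward to a set of distances and
clipped to the reserve's alongshore extent; coverage of the cohort's core
areas is reported for the union (total core habitat) and the intersection
(minimal candidate core area) of individual 50 % contours.

Containment uses the strict interior; points on a shared boundary are
assigned to the first-declared region.  All areas are km^2 in a local
equal-area projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce

import numpy as np
import pandas as pd
from shapely import contains_xy, intersects_xy
from shapely.geometry import Polygon
from shapely.ops import unary_union

from ._geo import AzimuthalEqualArea, project_geometry
from .io_formats import NamedRegionSet
from .preprocessing import RegularTrack

DEFAULT_BUFFERS_KM = (2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20)


@dataclass
class BufferScenario:
    reserve: Polygon           # lon/lat
    coast: Polygon             # land polygon, lon/lat
    distances_km: tuple = DEFAULT_BUFFERS_KM

    def __post_init__(self):
        d = np.asarray(self.distances_km, dtype=float)
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("buffer distances must be positive and increasing")


def polygon_area_km2(geom_lonlat) -> float:
    """Area of a lon/lat polygon via a local equal-area projection."""
    if geom_lonlat.is_empty:
        return 0.0
    c = geom_lonlat.centroid
    proj = AzimuthalEqualArea(c.x, c.y)
    return float(project_geometry(geom_lonlat, proj).area)


def time_in_region(track: RegularTrack, polygon) -> float:
    """Percent of grid points strictly inside the polygon."""
    if len(track.times) == 0:
        return float("nan")
    inside = contains_xy(polygon, track.lon, track.lat)
    return 100.0 * float(inside.sum()) / len(track.times)


def build_buffer(scenario: BufferScenario, d_km: float) -> Polygon:
    """Marine buffer to ``d_km`` from the coast along the reserve's shoreline.

    The coastline segment adjacent to the reserve is buffered seaward (land
    subtracted) and clipped laterally to the wedge spanned by the reserve's
    alongshore extent, seen from the land centroid.  Distances are computed
    in a local equal-area projection (geodesic error well under 2 % at this
    scale).  Returns a lon/lat polygon.
    """
    c = scenario.reserve.centroid
    proj = AzimuthalEqualArea(c.x, c.y)
    land = project_geometry(scenario.coast, proj)
    reserve = project_geometry(scenario.reserve, proj)
    coast_line = land.boundary.intersection(reserve.buffer(0.05))
    if coast_line.is_empty:
        raise ValueError("reserve does not touch the coastline")
    buf = coast_line.buffer(d_km).difference(land)
    # lateral clip: fan of rays from the island centroid through the
    # alongshore extent of the reserve's coast segment
    centre = np.array([land.centroid.x, land.centroid.y])
    pts = []
    for geom in getattr(coast_line, "geoms", [coast_line]):
        pts.extend(np.asarray(geom.coords))
    pts = np.asarray(pts)
    ang = np.arctan2(pts[:, 1] - centre[1], pts[:, 0] - centre[0])
    ang = np.unwrap(np.sort(ang))
    lo, hi = ang[0], ang[-1]
    fan = np.linspace(lo, hi, 16)
    far = 50.0 * (np.abs(d_km) + np.linalg.norm(pts[0] - centre))
    wedge = Polygon(np.vstack([centre,
                               centre + far * np.column_stack([np.cos(fan),
                                                               np.sin(fan)])]))
    clipped = buf.intersection(wedge)
    return project_geometry(clipped, proj, "inverse")


def core_union_intersection(core_polygons: list):
    """(n-ary union, n-ary intersection) of individual core-area polygons."""
    polys = [p for p in core_polygons if p is not None and not p.is_empty]
    if not polys:
        return Polygon(), Polygon()
    union = unary_union(polys)
    inter = reduce(lambda a, b: a.intersection(b), polys)
    return union, inter


@dataclass
class CoverageReport:
    per_animal: pd.DataFrame   # animal_id, distance_km, pct_time_inside
    per_scenario: pd.DataFrame  # distance_km, mean/sd pct_time, core coverages
    union_area_km2: float = 0.0
    intersection_area_km2: float = 0.0
    extra: dict = field(default_factory=dict)


def coverage_report(tracks: list, cores: list, scenario: BufferScenario,
                    extra_polygons: dict | None = None) -> CoverageReport:
    """Coverage metrics for every buffer distance (and optional user
    polygons, e.g. an externally proposed reserve extension).

    ``tracks`` are inter-nesting RegularTracks; ``cores`` the matching 50 %
    contour polygons (lon/lat; None allowed for animals without a UD).
    """
    union, inter = core_union_intersection(cores)
    a_union = polygon_area_km2(union)
    a_inter = polygon_area_km2(inter)
    rows, srows = [], []

    def eval_polygon(label, poly):
        pts = [time_in_region(tr, poly) for tr in tracks]
        cov_i = (100.0 * polygon_area_km2(inter.intersection(poly)) / a_inter
                 if a_inter > 0 else np.nan)
        cov_u = (100.0 * polygon_area_km2(union.intersection(poly)) / a_union
                 if a_union > 0 else np.nan)
        return pts, cov_i, cov_u

    for d in scenario.distances_km:
        poly = build_buffer(scenario, d)
        pts, cov_i, cov_u = eval_polygon(d, poly)
        for tr, p in zip(tracks, pts):
            rows.append({"animal_id": tr.animal_id, "distance_km": d,
                         "pct_time_inside": p})
        arr = np.asarray(pts, dtype=float)
        srows.append({"distance_km": d,
                      "pct_time_mean": float(np.nanmean(arr)),
                      "pct_time_sd": float(np.nanstd(arr, ddof=1))
                      if np.isfinite(arr).sum() > 1 else np.nan,
                      "pct_core_intersection_covered": cov_i,
                      "pct_core_union_covered": cov_u})
    report = CoverageReport(per_animal=pd.DataFrame(rows),
                            per_scenario=pd.DataFrame(srows),
                            union_area_km2=a_union,
                            intersection_area_km2=a_inter)
    for label, poly in (extra_polygons or {}).items():
        pts, cov_i, cov_u = eval_polygon(label, poly)
        arr = np.asarray(pts, dtype=float)
        report.extra[label] = {
            "pct_time_mean": float(np.nanmean(arr)),
            "pct_core_intersection_covered": cov_i,
            "pct_core_union_covered": cov_u,
        }
    return report


def eez_residency(tracks: list, regions: NamedRegionSet) -> pd.DataFrame:
    """Percent of grid points per named EEZ plus the high-seas remainder.

    Each point is assigned to at most one EEZ; boundary points go to the
    first-declared region.  Percentages partition to 100 per animal.
    """
    eezs = regions.by_kind("eez")
    rows = []
    for tr in tracks:
        n = len(tr.times)
        unassigned = np.ones(n, dtype=bool)
        row = {"animal_id": tr.animal_id}
        for r in eezs:
            hit = intersects_xy(r.geometry, tr.lon, tr.lat) & unassigned
            unassigned &= ~hit
            row[r.name] = 100.0 * float(hit.sum()) / n if n else np.nan
        row["high_seas"] = 100.0 * float(unassigned.sum()) / n if n else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    cohort = {"animal_id": "cohort_mean"}
    for c in df.columns[1:]:
        cohort[c] = float(df[c].mean())
    return pd.concat([df, pd.DataFrame([cohort])], ignore_index=True)
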