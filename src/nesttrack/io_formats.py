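"""Readers and writers for the pipeline's external file formats.

Four file types are handled, all plain text:

* Argos-style location tables — CSV with columns
  ``animal_id,timestamp,lon,lat,loc_class`` (ISO-8601 timestamps, UTC).
* Hourly tag dry-time timelines — CSV ``animal_id,hour_start,pct_dry``.
* Named region polygons (land, reserve, EEZs) — GeoJSON FeatureCollection
  with ``name`` and ``kind`` properties.
* Gridded monthly fishing-effort tables — CSV ``lat,lon,gear,month,hours``
  with the cell size declared in a ``# cell_size=...`` header comment.

Everything is validated on ingestion; rows are never silently altered —
dropped duplicates are counted and logged, out-of-range values raise.
Timestamps without an explicit zone are interpreted as UTC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

#: Argos location-quality classes, best (3, ~0.4 km error) to worst (Z).
ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")

REGION_KINDS = ("land", "reserve", "eez", "beach", "other")

GEARS = ("longline", "purse_seine")


class FormatError(ValueError):
    """Structurally malformed input file (missing column, bad geometry...)."""


class ValidationError(ValueError):
    """Well-formed file containing out-of-contract values."""


def _to_utc(series: pd.Series, colname: str, path) -> pd.Series:
    out = pd.to_datetime(series, utc=True, format="ISO8601", errors="coerce")
    if out.isna().any():
        line = int(np.flatnonzero(out.isna().to_numpy())[0]) + 2  # header is line 1
        raise FormatError(f"{path}: unparseable {colname} at line {line}")
    return out


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        if c not in df.columns:
            raise FormatError(f"{path}: missing required column '{c}'")


def read_argos_csv(path) -> pd.DataFrame:
    """Read an Argos location table.

    Returns a DataFrame with columns ``animal_id, timestamp, lon, lat,
    loc_class`` sorted by (animal_id, timestamp); exact duplicate rows are
    dropped (count logged).  Longitudes must already lie in [-180, 180];
    tracks crossing the antimeridian are rejected (the supported study
    region is Atlantic).
    """
    df = pd.read_csv(path, dtype={"animal_id": str, "loc_class": str})
    _require_columns(df, ["animal_id", "timestamp", "lon", "lat", "loc_class"], path)
    df["timestamp"] = _to_utc(df["timestamp"], "timestamp", path)
    bad = ~df["loc_class"].isin(ARGOS_CLASSES)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(
            f"{path}: invalid loc_class {df['loc_class'][bad].iloc[0]!r} at line {line}")
    lon = df["lon"].to_numpy(float)
    lat = df["lat"].to_numpy(float)
    if np.any(lon < -180) or np.any(lon > 180) or np.any(np.abs(lat) > 90):
        raise ValidationError(f"{path}: lon/lat outside valid WGS84 ranges")
    n0 = len(df)
    df = df.drop_duplicates()
    if len(df) < n0:
        logger.info("read_argos_csv(%s): dropped %d exact duplicate rows",
                    path, n0 - len(df))
    df = df.sort_values(["animal_id", "timestamp"], kind="stable").reset_index(drop=True)
    for _, g in df.groupby("animal_id", sort=False):
        dlon = np.abs(np.diff(g["lon"].to_numpy(float)))
        if np.any(dlon > 180):
            raise ValidationError(
                f"{path}: track for {g['animal_id'].iloc[0]} crosses the antimeridian "
                "(unsupported)")
    return df


def read_drytime_csv(path) -> pd.DataFrame:
    """Read hourly percent-dry timelines; returns ``animal_id, hour_start,
    pct_dry`` sorted ascending within animal.  Values outside [0, 100] raise
    (never clamped); gaps between hours are allowed."""
    df = pd.read_csv(path, dtype={"animal_id": str})
    _require_columns(df, ["animal_id", "hour_start", "pct_dry"], path)
    df["hour_start"] = _to_utc(df["hour_start"], "hour_start", path)
    v = df["pct_dry"].to_numpy(float)
    if np.any(~np.isfinite(v)) or np.any(v < 0) or np.any(v > 100):
        raise ValidationError(f"{path}: pct_dry outside [0, 100]")
    df = df.sort_values(["animal_id", "hour_start"], kind="stable").reset_index(drop=True)
    return df


@dataclass
class Region:
    name: str
    kind: str  # one of REGION_KINDS
    geometry: object  # shapely geometry, lon/lat


@dataclass
class NamedRegionSet:
    """Named polygons (land, reserve, EEZs...) with unique names.

    Declaration order is meaningful: boundary-point ties in point-in-polygon
    assignments go to the first-declared region.
    """

    regions: list = field(default_factory=list)

    def names(self):
        return [r.name for r in self.regions]

    def get(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def by_kind(self, kind: str):
        return [r for r in self.regions if r.kind == kind]

    def add(self, name, kind, geometry):
        if name in self.names():
            raise ValidationError(f"duplicate region name {name!r}")
        if kind not in REGION_KINDS:
            raise ValidationError(f"unknown region kind {kind!r}")
        self.regions.append(Region(name, kind, geometry))


def read_regions(path) -> NamedRegionSet:
    """Read a GeoJSON FeatureCollection of named regions.

    Invalid geometries are repaired with ``make_valid``; a geometry still
    invalid (or empty) after repair raises, naming the region.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    out = NamedRegionSet()
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        name = props.get("name")
        kind = props.get("kind")
        if name is None or kind is None:
            raise FormatError(f"{path}: feature missing 'name'/'kind' properties")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            geom = make_valid(geom)
        if not geom.is_valid or geom.is_empty:
            raise FormatError(f"{path}: region {name!r} has invalid geometry")
        out.add(name, kind, geom)
    return out


def write_regions(regions: NamedRegionSet, path) -> None:
    feats = [
        {"type": "Feature",
         "properties": {"name": r.name, "kind": r.kind},
         "geometry": mapping(r.geometry)}
        for r in regions.regions
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


@dataclass
class EffortGrid:
    """Monthly gridded fishing effort.

    ``cells`` has columns ``lat, lon, gear, month, hours`` where (lat, lon)
    is the cell's lower-left corner (a multiple of ``cell_size``), ``month``
    is a 'YYYY-MM' string and hours are non-negative.
    """

    cell_size: float
    cells: pd.DataFrame

    def total_hours(self) -> float:
        return float(self.cells["hours"].sum())


def _check_bin_edges(values, cell_size, what, path):
    r = np.abs(values / cell_size - np.round(values / cell_size))
    if np.any(r > 1e-6):
        i = int(np.flatnonzero(r > 1e-6)[0])
        raise ValidationError(
            f"{path}: {what}={values[i]} is not a multiple of cell_size={cell_size}")


def read_effort_csv(path, cell_size: float | None = None) -> EffortGrid:
    """Read a monthly fishing-effort grid.

    The cell size may be declared in a ``# cell_size=0.1`` comment on the
    first line or passed explicitly; explicit wins.
    """
    if cell_size is None:
        with open(path) as fh:
            first = fh.readline().strip()
        if first.startswith("#") and "cell_size" in first:
            cell_size = float(first.split("=", 1)[1])
        else:
            raise FormatError(f"{path}: cell_size neither declared nor given")
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["lat", "lon", "gear", "month", "hours"], path)
    if not df["gear"].isin(GEARS).all():
        raise ValidationError(f"{path}: unknown gear value")
    h = df["hours"].to_numpy(float)
    if np.any(h < 0) or np.any(~np.isfinite(h)):
        raise ValidationError(f"{path}: negative or non-finite hours")
    _check_bin_edges(df["lat"].to_numpy(float), cell_size, "lat", path)
    _check_bin_edges(df["lon"].to_numpy(float), cell_size, "lon", path)
    # normalize month to YYYY-MM
    df["month"] = pd.PeriodIndex(df["month"], freq="M").astype(str)
    return EffortGrid(cell_size=float(cell_size), cells=df.reset_index(drop=True))


def write_effort_csv(grid: EffortGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cell_size={grid.cell_size}\n")
        grid.cells.to_csv(fh, index=False)


def write_table(rows, path) -> None:
    """Write a table (DataFrame or list of dicts) as plain CSV with header."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def format_date(ts) -> str:
    """Render a date as DD/MM/YYYY (reporting convention)."""
    return pd.Timestamp(ts).strftime("%d/%m/%Y")
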