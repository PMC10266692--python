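"""Spherical-earth distance and small local map projections.

All great-circle distances in the package go through :func:`haversine_km`
(sphere of radius 6371 km).  Planar geometry (buffers, areas, kernel grids)
is done in one of two local projections centred on the study area:

* :class:`LocalEquirect` — tangent-plane equirectangular, used for movement
  simulation and state-space smoothing where distances within a few hundred
  km of the centre are what matter (distortion < 0.5 % within 500 km at low
  latitude).
* :class:`AzimuthalEqualArea` — Lambert azimuthal equal-area, used wherever
  an area in km^2 is reported (utilization distributions, reserve buffers).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def track_speeds_ms(timestamps, lon, lat):
    """Speeds (m/s) between consecutive fixes; length n-1.

    ``timestamps`` is array-like of numpy datetime64 / pandas Timestamps.
    Zero time gaps yield ``inf`` speed unless the step distance is also zero.
    """
    t = pd.DatetimeIndex(timestamps).asi8 / 1e9
    d_m = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:]) * 1000.0
    dt = np.diff(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(dt > 0, d_m / np.where(dt > 0, dt, 1.0),
                     np.where(d_m > 0, np.inf, 0.0))
    return v


class LocalEquirect:
    """Equirectangular tangent plane about (lon0, lat0); coordinates in km."""

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._coslat = np.cos(np.radians(lat0))
        self._k = EARTH_RADIUS_KM * np.pi / 180.0

    def forward(self, lon, lat):
        x = (np.asarray(lon, dtype=float) - self.lon0) * self._k * self._coslat
        y = (np.asarray(lat, dtype=float) - self.lat0) * self._k
        return x, y

    def inverse(self, x, y):
        lon = self.lon0 + np.asarray(x, dtype=float) / (self._k * self._coslat)
        lat = self.lat0 + np.asarray(y, dtype=float) / self._k
        return lon, lat


class AzimuthalEqualArea:
    """Lambert azimuthal equal-area projection about (lon0, lat0), in km.

    Areas computed on projected polygons are exact on the sphere; shape
    distortion is negligible within a few hundred km of the centre.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = np.radians(float(lon0))
        self.lat0 = np.radians(float(lat0))

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        c0, s0 = np.cos(self.lat0), np.sin(self.lat0)
        dl = lam - self.lon0
        denom = 1.0 + s0 * np.sin(phi) + c0 * np.cos(phi) * np.cos(dl)
        denom = np.maximum(denom, 1e-12)
        k = EARTH_RADIUS_KM * np.sqrt(2.0 / denom)
        x = k * np.cos(phi) * np.sin(dl)
        y = k * (c0 * np.sin(phi) - s0 * np.cos(phi) * np.cos(dl))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        rho = np.sqrt(x ** 2 + y ** 2)
        c = 2.0 * np.arcsin(np.minimum(1.0, rho / 2.0))
        c0, s0 = np.cos(self.lat0), np.sin(self.lat0)
        with np.errstate(invalid="ignore"):
            phi = np.where(
                rho > 1e-15,
                np.arcsin(np.cos(c) * s0 + y * np.sin(c) * c0 / np.maximum(rho, 1e-15)),
                self.lat0,
            )
            lam = self.lon0 + np.arctan2(
                x * np.sin(c),
                rho * c0 * np.cos(c) - y * s0 * np.sin(c),
            )
        return np.degrees(lam), np.degrees(phi)


def project_geometry(geom, proj, direction: str = "forward"):
    """Apply a local projection to a shapely geometry (lon/lat <-> km)."""
    from shapely.ops import transform

    fn = proj.forward if direction == "forward" else proj.inverse

    def _t(a, b):
        return fn(np.asarray(a), np.asarray(b))

    return transform(_t, geom)


def destination(lon, lat, bearing_deg, dist_km):
    """Point reached from (lon, lat) on the given initial bearing, on the sphere."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    d = np.asarray(dist_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat1) * np.cos(d) + np.cos(lat1) * np.sin(d) * np.cos(brg))
    lon2 = lon1 + np.arctan2(np.sin(brg) * np.sin(d) * np.cos(lat1),
                             np.cos(d) - np.sin(lat1) * np.sin(lat2))
    return np.degrees(lon2), np.degrees(lat2)
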