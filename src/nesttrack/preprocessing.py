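"""Argos track filtering and state-space regularization.

Filtering follows the standard telemetry recipe: drop the unusable location
classes (LC 0 and Z by default, keeping A and B despite their large error —
flagged for users), drop positions on land during the inter-nesting phase,
and drop fixes implying speeds over 15 m/s with a deterministic forward
sweep.

Regularization replaces a Bayesian hierarchical first-difference correlated
random walk (MCMC) with a deterministic maximum-likelihood analogue: a
continuous-time correlated-velocity process (integrated Ornstein-Uhlenbeck
velocity) fitted per animal by maximizing the Kalman-filter likelihood,
with measurement error fixed per Argos class, then smoothed (RTS) and
evaluated on an exact fixed-interval grid.  Same role — error-corrected
positions on a regular grid with per-point uncertainty — without MCMC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from shapely import contains_xy

from ._geo import LocalEquirect, track_speeds_ms
from .synthetic import _DEF_ERROR_SD

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    drop_classes: frozenset = frozenset({"0", "Z"})
    vmax: float = 15.0                  # m/s speed ceiling
    land_filter_phase: bool = True      # land removal only during inter-nesting

    def __post_init__(self):
        if self.vmax <= 0:
            raise ValueError("vmax must be > 0")


@dataclass
class RegularTrack:
    """Per-animal positions on an exact fixed-interval time grid."""

    animal_id: str
    times: pd.DatetimeIndex
    lon: np.ndarray
    lat: np.ndarray
    sd_km: np.ndarray       # per-point position sd from the smoother
    delta: pd.Timedelta

    def __post_init__(self):
        if len(self.times) > 1:
            gaps = np.diff(self.times.asi8)
            if not np.all(gaps == self.delta.value):
                raise ValueError("grid timestamps must differ by exactly delta")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"animal_id": self.animal_id, "timestamp": self.times,
                             "lon": self.lon, "lat": self.lat, "sd_km": self.sd_km})

    def slice_time(self, start=None, end=None) -> "RegularTrack":
        m = np.ones(len(self.times), dtype=bool)
        if start is not None:
            m &= self.times >= pd.Timestamp(start)
        if end is not None:
            m &= self.times <= pd.Timestamp(end)
        return RegularTrack(self.animal_id, self.times[m], self.lon[m],
                            self.lat[m], self.sd_km[m], self.delta)


# ---------------------------------------------------------------------------
# Filters


def filter_classes(locs: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Drop fixes whose location class is in ``cfg.drop_classes``."""
    out = locs[~locs["loc_class"].isin(cfg.drop_classes)].reset_index(drop=True)
    if len(out) == 0 and len(locs) > 0:
        warnings.warn(f"all {len(locs)} locations dropped by class filter "
                      f"(animal {locs['animal_id'].iloc[0]})")
    return out


def filter_speed(locs: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Forward-sweep speed filter.

    Walks the track keeping a fix only if the great-circle speed from the
    last kept fix is <= vmax; the downstream member of each violating pair
    is dropped.  A single pass reaches the fixpoint, so the post-condition
    (all consecutive retained speeds <= vmax) holds by construction and the
    filter is idempotent.
    """
    n = len(locs)
    if n < 2:
        return locs.reset_index(drop=True)
    t = locs["timestamp"].to_numpy()
    lon = locs["lon"].to_numpy(float)
    lat = locs["lat"].to_numpy(float)
    keep = [0]
    for i in range(1, n):
        j = keep[-1]
        v = track_speeds_ms(t[[j, i]], lon[[j, i]], lat[[j, i]])[0]
        if v <= cfg.vmax:
            keep.append(i)
    if len(keep) < n:
        logger.info("filter_speed: dropped %d of %d fixes", n - len(keep), n)
    return locs.iloc[keep].reset_index(drop=True)


def filter_on_land(locs: pd.DataFrame, land_geometry,
                   internesting_window: tuple | None = None) -> pd.DataFrame:
    """Drop fixes strictly inside land during the inter-nesting window.

    ``internesting_window`` is (start, end); ``None`` applies the filter to
    the whole track (the two-pass convention: before segmentation the
    migration start is unknown, afterwards the filter is re-scoped).
    Boundary points are retained (strict-interior test).
    """
    inside = contains_xy(land_geometry, locs["lon"].to_numpy(float),
                         locs["lat"].to_numpy(float))
    if internesting_window is not None:
        def _utc(x):
            ts = pd.Timestamp(x)
            return ts.tz_localize("UTC") if ts.tzinfo is None else ts
        s, e = internesting_window
        in_win = np.ones(len(locs), dtype=bool)
        if s is not None:
            in_win &= (locs["timestamp"] >= _utc(s)).to_numpy()
        if e is not None:
            in_win &= (locs["timestamp"] < _utc(e)).to_numpy()
        inside &= in_win
    if inside.any():
        logger.info("filter_on_land: dropped %d fixes on land", int(inside.sum()))
    return locs[~inside].reset_index(drop=True)


def apply_filters(locs: pd.DataFrame, cfg: FilterConfig, land_geometry=None,
                  internesting_window=None) -> pd.DataFrame:
    out = filter_classes(locs, cfg)
    if land_geometry is not None:
        out = filter_on_land(out, land_geometry, internesting_window)
    out = filter_speed(out, cfg)
    return out


# ---------------------------------------------------------------------------
# Correlated-velocity state-space smoother


def ctcrw_matrices(beta: float, sigma2: float, dt: np.ndarray):
    """Exact discretization of the integrated-OU velocity model.

    State is [position, velocity] per coordinate; velocity follows
    dv = -beta v dt + sigma dW.  Returns transition matrices T (n,2,2) and
    process covariances Q (n,2,2) for an array of time steps ``dt``.
    """
    dt = np.asarray(dt, dtype=float)
    a = np.exp(-beta * dt)
    T = np.zeros(dt.shape + (2, 2))
    T[..., 0, 0] = 1.0
    T[..., 0, 1] = (1.0 - a) / beta
    T[..., 1, 1] = a
    Q = np.zeros_like(T)
    Q[..., 1, 1] = sigma2 * (1.0 - a ** 2) / (2.0 * beta)
    Q[..., 0, 1] = Q[..., 1, 0] = sigma2 * (1.0 - a) ** 2 / (2.0 * beta ** 2)
    Q[..., 0, 0] = sigma2 / beta ** 2 * (
        dt - 2.0 * (1.0 - a) / beta + (1.0 - a ** 2) / (2.0 * beta))
    return T, Q


_H = np.array([[1.0, 0.0]])


def _kalman(times_h, y, r, beta, sigma2, p0_pos, obs_mask=None, smooth=False):
    """Kalman filter (and optional RTS smoother) for both coordinates.

    ``y`` is (n, 2) with NaN rows allowed where ``obs_mask`` is False,
    ``r`` the per-time measurement variance (km^2).  Returns the total
    log-likelihood over observed rows, and if ``smooth`` the smoothed
    position means (n, 2) and position variances (n, 2).
    """
    n = len(times_h)
    dt = np.diff(times_h)
    T, Q = ctcrw_matrices(beta, sigma2, np.maximum(dt, 1e-9))
    if obs_mask is None:
        obs_mask = np.ones(n, dtype=bool)
    first_obs = int(np.flatnonzero(obs_mask)[0])
    pvel = sigma2 / (2.0 * beta)
    m = np.zeros((2, 2))          # state rows = [pos, vel], columns = x/y coord
    m[0] = y[first_obs]
    P = np.diag([p0_pos, pvel])
    ll = 0.0
    mf = np.zeros((n, 2, 2))      # filtered means
    Pf = np.zeros((n, 2, 2))      # filtered covariances (shared by x and y)
    mp = np.zeros((n, 2, 2))      # one-step predictions
    Pp = np.zeros((n, 2, 2))
    for k in range(n):
        if k > 0:
            Tk, Qk = T[k - 1], Q[k - 1]
            m = Tk @ m
            P = Tk @ P @ Tk.T + Qk
        mp[k], Pp[k] = m, P
        if obs_mask[k]:
            S = P[0, 0] + r[k]
            v = y[k] - m[0]
            ll += -0.5 * (2 * np.log(2 * np.pi * S) + (v @ v) / S)
            K = P[:, 0] / S
            m = m + np.outer(K, v)
            P = P - np.outer(K, P[0, :])
            P = 0.5 * (P + P.T)
        mf[k], Pf[k] = m, P
    if not smooth:
        return ll, None, None
    # RTS backward pass (gain shared by both coordinates)
    sm = mf.copy()
    sP = Pf.copy()
    for k in range(n - 2, -1, -1):
        G = Pf[k] @ T[k].T @ np.linalg.inv(Pp[k + 1])
        sm[k] = mf[k] + G @ (sm[k + 1] - mp[k + 1])
        sP[k] = Pf[k] + G @ (sP[k + 1] - Pp[k + 1]) @ G.T
        sP[k] = 0.5 * (sP[k] + sP[k].T)
    pos_mean = sm[:, 0, :]
    pos_var = np.maximum(sP[:, 0, 0], 0.0)
    return ll, pos_mean, np.column_stack([pos_var, pos_var])


def _kalman_rw(times_h, y, r, sigma2, p0_pos, obs_mask=None, smooth=False):
    """Random-walk (position-only) fallback filter/smoother."""
    n = len(times_h)
    dt = np.maximum(np.diff(times_h), 1e-9)
    if obs_mask is None:
        obs_mask = np.ones(n, dtype=bool)
    first_obs = int(np.flatnonzero(obs_mask)[0])
    m = y[first_obs].copy()
    P = p0_pos
    ll = 0.0
    mf = np.zeros((n, 2))
    Pf = np.zeros(n)
    mp = np.zeros((n, 2))
    Pp = np.zeros(n)
    for k in range(n):
        if k > 0:
            P = P + sigma2 * dt[k - 1]
        mp[k], Pp[k] = m, P
        if obs_mask[k]:
            S = P + r[k]
            v = y[k] - m
            ll += -0.5 * (2 * np.log(2 * np.pi * S) + (v @ v) / S)
            K = P / S
            m = m + K * v
            P = (1 - K) * P
        mf[k], Pf[k] = m, P
    if not smooth:
        return ll, None, None
    sm = mf.copy()
    sP = Pf.copy()
    for k in range(n - 2, -1, -1):
        G = Pf[k] / Pp[k + 1]
        sm[k] = mf[k] + G * (sm[k + 1] - mp[k + 1])
        sP[k] = Pf[k] + G ** 2 * (sP[k + 1] - Pp[k + 1])
    return ll, sm, np.column_stack([sP, sP])


def regularize(locs: pd.DataFrame, delta, error_sds_per_class: dict | None = None,
               p0_pos_var: float = 1e4) -> RegularTrack:
    """Fit the correlated-velocity smoother and evaluate it on an exact grid.

    ``delta`` is the output interval (e.g. "4h" or "1D"); the grid runs from
    the first fix in steps of exactly ``delta`` up to the last fix.  The
    reversion rate and process variance are estimated by maximum likelihood
    (Nelder-Mead on log parameters); if the optimizer fails the smoother
    falls back to a random-walk position model with a warning.
    Requires >= 8 fixes spanning >= 2 * delta.
    """
    if error_sds_per_class is None:
        error_sds_per_class = dict(_DEF_ERROR_SD)
    delta = pd.Timedelta(delta)
    if len(locs) < 8:
        raise ValueError("regularize needs >= 8 filtered locations")
    t = pd.DatetimeIndex(locs["timestamp"])
    if t[-1] - t[0] < 2 * delta:
        raise ValueError("track span shorter than 2 * delta")
    animal_id = str(locs["animal_id"].iloc[0])

    proj = LocalEquirect(float(locs["lon"].mean()), float(locs["lat"].mean()))
    x, ykm = proj.forward(locs["lon"].to_numpy(float), locs["lat"].to_numpy(float))
    yobs = np.column_stack([x, ykm])
    robs = np.array([error_sds_per_class[c] ** 2 for c in locs["loc_class"]])
    tobs_h = (t.asi8 - t.asi8[0]) / 3.6e12

    # collapse simultaneous fixes (keep the more precise one)
    order = np.argsort(tobs_h, kind="stable")
    tobs_h, yobs, robs = tobs_h[order], yobs[order], robs[order]
    uniq = np.concatenate([[True], np.diff(tobs_h) > 1e-9])
    tobs_h, yobs, robs = tobs_h[uniq], yobs[uniq], robs[uniq]

    step_v = track_speeds_ms(t, locs["lon"].to_numpy(float),
                             locs["lat"].to_numpy(float))
    v_kmh = np.nanmedian(step_v[np.isfinite(step_v)]) * 3.6 if len(step_v) else 1.0
    v_kmh = max(v_kmh, 0.1)

    def nll(params):
        lb, ls = params
        if not (-9.5 < lb < 2.5) or not (-14.0 < ls < 8.0):
            return 1e12
        ll, _, _ = _kalman(tobs_h, yobs, robs, np.exp(lb), np.exp(ls),
                           p0_pos_var)
        return -ll if np.isfinite(ll) else 1e12

    beta0 = 1.0 / 6.0                       # ~6 h velocity decorrelation
    sigma20 = max(v_kmh ** 2 * 2 * beta0, 1e-6)
    res = minimize(nll, np.array([np.log(beta0), np.log(sigma20)]),
                   method="Nelder-Mead",
                   options={"maxiter": 300, "xatol": 1e-3, "fatol": 1e-4})
    fallback = (not res.success and not np.isfinite(res.fun)) or res.fun >= 1e12

    grid = pd.date_range(t[0], t[-1], freq=delta)
    tgrid_h = (grid.asi8 - t.asi8[0]) / 3.6e12
    all_t = np.concatenate([tobs_h, tgrid_h])
    all_y = np.vstack([yobs, np.full((len(tgrid_h), 2), np.nan)])
    all_r = np.concatenate([robs, np.zeros(len(tgrid_h))])
    mask = np.concatenate([np.ones(len(tobs_h), bool), np.zeros(len(tgrid_h), bool)])
    gid = np.concatenate([np.full(len(tobs_h), -1), np.arange(len(tgrid_h))])
    order = np.argsort(all_t, kind="stable")
    all_t, all_y, all_r = all_t[order], all_y[order], all_r[order]
    mask, gid = mask[order], gid[order]

    if not fallback:
        beta, sigma2 = np.exp(res.x)
        _, pos, var = _kalman(all_t, all_y, all_r, beta, sigma2, p0_pos_var,
                              obs_mask=mask, smooth=True)
    else:
        warnings.warn(f"regularize({animal_id}): correlated-velocity fit did "
                      "not converge; falling back to random-walk smoother")
        def nll_rw(ls):
            ll, _, _ = _kalman_rw(tobs_h, yobs, robs, np.exp(ls[0]), p0_pos_var)
            return -ll if np.isfinite(ll) else 1e12
        r2 = minimize(nll_rw, [np.log(max(v_kmh ** 2, 1e-4))],
                      method="Nelder-Mead", options={"maxiter": 200})
        _, pos, var = _kalman_rw(all_t, all_y, all_r, float(np.exp(r2.x[0])),
                                 p0_pos_var, obs_mask=mask, smooth=True)

    sel = gid >= 0
    gpos = np.empty((len(tgrid_h), 2))
    gvar = np.empty(len(tgrid_h))
    gpos[gid[sel]] = pos[sel]
    gvar[gid[sel]] = var[sel, 0]
    lon, lat = proj.inverse(gpos[:, 0], gpos[:, 1])
    return RegularTrack(animal_id=animal_id, times=grid, lon=np.asarray(lon),
                        lat=np.asarray(lat), sd_km=np.sqrt(np.maximum(gvar, 0.0)),
                        delta=delta)
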