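"""Continuous-time movement models and utilization distributions.

Inter-nesting tracks are fitted with the standard family of stationary
Gaussian movement processes — IID (no autocorrelation), OU (autocorrelated
position, timescale tau_p) and OUF (autocorrelated position and velocity,
timescales tau_p > tau_v) — each optionally with a periodic mean (one
sine/cosine harmonic at the inter-nesting period, default 11.5 d) to absorb
the cyclical to-and-from-the-beach movements.  Likelihoods are evaluated by
Kalman filtering on the state-space form, with per-point measurement error
taken from the regularized track; mean coefficients are profiled out by
filtering the regression basis alongside the data (GLS through the filter).
The lowest-AIC model wins; near-ties (delta AIC < 4) go to the model with
fewest parameters.

The utilization distribution is a Gaussian kernel density over the track in
a local equal-area projection, with bandwidth H = Sigma_hat * N_eff^(-1/3)
where N_eff is the effective number of independent locations implied by the
fitted position-autocorrelation time (track duration / tau_p, capped at n;
N_eff = n for IID).  Core area and home range are the 50 % and 95 %
highest-density contours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm, solve_continuous_lyapunov
from scipy.optimize import minimize
from shapely.geometry import Polygon
from shapely.ops import unary_union
from skimage import measure

from ._geo import AzimuthalEqualArea
from .preprocessing import RegularTrack

MODELS = ("iid", "ou", "ouf")


@dataclass
class MovementModelFit:
    model: str                 # "iid" | "ou" | "ouf"
    periodic: bool
    params: dict               # sigma2_x/y (km^2), tau_p/tau_v (h), beta_x/y
    loglik: float
    k: int                     # parameter count
    aic: float
    n: int
    duration_h: float

    def n_eff(self) -> float:
        if self.model == "iid":
            return float(self.n)
        tau = self.params["tau_p"]
        return float(min(self.n, max(1.0, self.duration_h / tau)))


def _ouf_discrete(tau_p, tau_v, sigma2, dt):
    """Exact discretization of the two-timescale (OUF) process.

    Companion form z = [x, x'] with poles -1/tau_p, -1/tau_v; the spectral
    density q is set so the stationary position variance is sigma2.
    Transition and process noise via the Van Loan augmented exponential.
    """
    A = np.array([[0.0, 1.0],
                  [-1.0 / (tau_p * tau_v), -(1.0 / tau_p + 1.0 / tau_v)]])
    q = 2.0 * sigma2 * (tau_p + tau_v) / (tau_p ** 2 * tau_v ** 2)
    LqL = np.array([[0.0, 0.0], [0.0, q]])
    M = np.zeros((4, 4))
    M[:2, :2] = -A
    M[:2, 2:] = LqL
    M[2:, 2:] = A.T
    E = expm(M * dt)
    T = E[2:, 2:].T
    Q = T @ E[:2, 2:]
    Q = 0.5 * (Q + Q.T)
    Pinf = solve_continuous_lyapunov(A, -LqL)
    return T, Q, 0.5 * (Pinf + Pinf.T)


def _innovations(times_h, Y, r, model, sigma2, tau_p=None, tau_v=None):
    """Innovations and their variances for every column of Y under the model.

    The Kalman gain sequence depends only on the covariance structure, so
    running the same recursion over the data column and the mean-basis
    columns yields the whitened versions of both (the GLS-through-the-filter
    device).  Returns (innovations (n, m), F (n,)).
    """
    n, m = Y.shape
    if model == "iid":
        return Y.copy(), sigma2 + r
    dts = np.diff(times_h)
    innov = np.zeros((n, m))
    F = np.zeros(n)
    if model == "ou":
        mean = np.zeros(m)
        P = sigma2
        prev_t = times_h[0]
        for k in range(n):
            if k > 0:
                a = np.exp(-(times_h[k] - prev_t) / tau_p)
                mean = a * mean
                P = a * a * P + sigma2 * (1.0 - a * a)
                prev_t = times_h[k]
            S = P + r[k]
            if not np.isfinite(S) or S <= 0:
                F[k:] = np.inf
                return innov, F
            innov[k] = Y[k] - mean
            F[k] = S
            K = P / S
            mean = mean + K * innov[k]
            P = P * (1.0 - K)
        return innov, F
    # ouf
    cache = {}
    _, _, Pinf = _ouf_discrete(tau_p, tau_v, sigma2, 1.0)
    mean = np.zeros((2, m))
    P = Pinf.copy()
    for k in range(n):
        if k > 0:
            dt = dts[k - 1]
            key = round(float(dt), 9)
            if key not in cache:
                T, Q, _ = _ouf_discrete(tau_p, tau_v, sigma2, dt)
                cache[key] = (T, Q)
            T, Q = cache[key]
            mean = T @ mean
            P = T @ P @ T.T + Q
        S = P[0, 0] + r[k]
        if not np.isfinite(S) or S <= 0:
            F[k:] = np.inf
            return innov, F
        innov[k] = Y[k] - mean[0]
        F[k] = S
        K = P[:, 0] / S
        mean = mean + np.outer(K, innov[k])
        P = P - np.outer(K, P[0, :])
        P = 0.5 * (P + P.T)
    return innov, F


def _profiled_loglik(times_h, y, r, X, model, sigma2, tau_p=None, tau_v=None):
    """Log-likelihood of one coordinate with mean coefficients profiled.

    ``X`` is the (n, p) mean basis or None for a fixed zero mean.  Returns
    (loglik, beta_hat).
    """
    if X is None:
        cols = y[:, None]
    else:
        cols = np.column_stack([y, X])
    innov, F = _innovations(times_h, cols, r, model, sigma2, tau_p, tau_v)
    if np.any(F <= 0) or np.any(~np.isfinite(F)):
        return -np.inf, None
    yt = innov[:, 0]
    if X is None:
        beta = np.zeros(0)
        resid = yt
    else:
        Xt = innov[:, 1:]
        W = 1.0 / F
        G = Xt.T @ (Xt * W[:, None])
        b = Xt.T @ (yt * W)
        try:
            beta = np.linalg.solve(G, b)
        except np.linalg.LinAlgError:
            return -np.inf, None
        resid = yt - Xt @ beta
    ll = -0.5 * np.sum(np.log(2.0 * np.pi * F) + resid ** 2 / F)
    return float(ll), beta


def _mean_basis(times_h, periodic, period_h):
    X = [np.ones_like(times_h)]
    if periodic:
        w = 2.0 * np.pi / period_h
        X += [np.sin(w * times_h), np.cos(w * times_h)]
    return np.column_stack(X)


def _fit_one(times_h, xy, r, model, periodic, period_h):
    X = _mean_basis(times_h, periodic, period_h)
    p_mean = X.shape[1]
    span = times_h[-1] - times_h[0]
    v0x = max(np.var(xy[:, 0]), 1e-4)
    v0y = max(np.var(xy[:, 1]), 1e-4)

    def unpack(params):
        s2x, s2y = np.exp(params[0]), np.exp(params[1])
        tau_p = tau_v = None
        if model in ("ou", "ouf"):
            tau_p = np.exp(params[2])
        if model == "ouf":
            u = 1.0 / (1.0 + np.exp(-params[3]))      # tau_v = u * tau_p < tau_p
            tau_v = max(u * tau_p, 1e-6) * 0.999
        return s2x, s2y, tau_p, tau_v

    def nll(params):
        if np.any(np.abs(params) > 30):
            return 1e12
        s2x, s2y, tau_p, tau_v = unpack(params)
        if tau_p is not None and not (1e-3 < tau_p < 100 * span):
            return 1e12
        ll = 0.0
        for axis, s2 in ((0, s2x), (1, s2y)):
            l, _ = _profiled_loglik(times_h, xy[:, axis], r, X, model,
                                    s2, tau_p, tau_v)
            if not np.isfinite(l):
                return 1e12
            ll += l
        return -ll

    x0 = [np.log(v0x), np.log(v0y)]
    if model in ("ou", "ouf"):
        x0.append(np.log(max(span / 10.0, 1.0)))
    if model == "ouf":
        x0.append(np.log(0.2 / 0.8))
    res = minimize(nll, np.array(x0), method="Nelder-Mead",
                   options={"maxiter": 400, "xatol": 1e-3, "fatol": 1e-4})
    if not np.isfinite(res.fun) or res.fun >= 1e12:
        raise RuntimeError(f"{model} fit did not converge")
    s2x, s2y, tau_p, tau_v = unpack(res.x)
    betas = {}
    ll = 0.0
    for axis, s2, name in ((0, s2x, "x"), (1, s2y, "y")):
        l, b = _profiled_loglik(times_h, xy[:, axis], r, X, model, s2,
                                tau_p, tau_v)
        ll += l
        betas[f"beta_{name}"] = b.tolist()
    k = 2 + {"iid": 0, "ou": 1, "ouf": 2}[model] + 2 * p_mean
    params = {"sigma2_x": s2x, "sigma2_y": s2y, "tau_p": tau_p, "tau_v": tau_v,
              **betas}
    return MovementModelFit(model=model, periodic=periodic, params=params,
                            loglik=float(ll), k=k, aic=2 * k - 2 * ll,
                            n=len(times_h), duration_h=float(span))


def fit_models(track: RegularTrack, period_days: float = 11.5,
               models=MODELS, include_periodic: bool = True) -> list:
    """Fit the movement-model family to an inter-nesting track.

    Requires >= 20 grid points.  Any single model that fails to converge is
    omitted with a warning; an empty result raises.
    """
    if len(track.times) < 20:
        raise ValueError("need >= 20 grid points to fit movement models")
    proj = AzimuthalEqualArea(float(np.mean(track.lon)), float(np.mean(track.lat)))
    x, y = proj.forward(track.lon, track.lat)
    xy = np.column_stack([x, y])
    times_h = (track.times.asi8 - track.times.asi8[0]) / 3.6e12
    r = np.maximum(track.sd_km, 1e-3) ** 2
    fits = []
    variants = [(m, p) for m in models
                for p in ((False, True) if include_periodic else (False,))]
    for model, periodic in variants:
        try:
            fits.append(_fit_one(times_h, xy, r, model, periodic,
                                 period_days * 24.0))
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"movement model {model}"
                          f"{'+periodic' if periodic else ''} omitted: {exc}")
    if not fits:
        raise RuntimeError("no movement model converged")
    return fits


def select_model(fits: list, delta_aic_tie: float = 4.0) -> MovementModelFit:
    """Lowest AIC; among fits within ``delta_aic_tie`` of the minimum the
    one with fewest parameters wins (parsimony in place of visual variogram
    inspection)."""
    best_aic = min(f.aic for f in fits)
    tied = [f for f in fits if f.aic - best_aic < delta_aic_tie]
    return min(tied, key=lambda f: (f.k, f.aic))


# ---------------------------------------------------------------------------
# Utilization distribution


@dataclass
class UDResult:
    proj: AzimuthalEqualArea
    x_edges: np.ndarray        # km
    y_edges: np.ndarray
    density: np.ndarray        # cell probability mass, sums to 1
    cell_area_km2: float
    contours: dict = field(default_factory=dict)
    # contours[level] = {"threshold", "polygons" (lon/lat), "polygons_km",
    #                    "area_km2"}
    n_eff: float = 0.0

    def area(self, level: float) -> float:
        return self.contours[level]["area_km2"]


def _hdr_threshold(mass: np.ndarray, level: float) -> float:
    flat = np.sort(mass.ravel())[::-1]
    cum = np.cumsum(flat)
    idx = int(np.searchsorted(cum, level))
    idx = min(idx, len(flat) - 1)
    return flat[idx]


def _contour_polygons(mass, x_cent, y_cent, threshold, proj):
    """Iso-line polygons at the threshold (cell-mass scale), via marching
    squares on a zero-padded grid so boundary-touching regions close."""
    dx = x_cent[1] - x_cent[0] if len(x_cent) > 1 else 1.0
    dy = y_cent[1] - y_cent[0] if len(y_cent) > 1 else 1.0
    padded = np.pad(mass, 1, constant_values=0.0)
    rings = measure.find_contours(padded.T, threshold)  # rows = y, cols = x
    polys = []
    for ring in rings:
        if len(ring) < 4:
            continue
        ykm = (ring[:, 0] - 1) * dy + y_cent[0]
        xkm = (ring[:, 1] - 1) * dx + x_cent[0]
        p = Polygon(np.column_stack([xkm, ykm]))
        if p.is_valid and p.area > 0:
            polys.append(p)
    merged = unary_union(polys) if polys else Polygon()
    from ._geo import project_geometry
    lonlat = project_geometry(merged, proj, "inverse") if not merged.is_empty \
        else merged
    return merged, lonlat


def _kde_mass(pts, H, x_cent, y_cent, chunk=2048):
    Hi = np.linalg.inv(H)
    det = np.linalg.det(H)
    gx, gy = np.meshgrid(x_cent, y_cent, indexing="ij")
    g = np.column_stack([gx.ravel(), gy.ravel()])
    dens = np.empty(len(g))
    for i in range(0, len(g), chunk):
        d = g[i:i + chunk, None, :] - pts[None, :, :]
        quad = (d @ Hi * d).sum(axis=2)
        dens[i:i + chunk] = np.exp(-0.5 * quad).sum(axis=1)
    dens /= 2 * np.pi * np.sqrt(det) * len(pts)
    return dens.reshape(len(x_cent), len(y_cent))


def estimate_ud(track: RegularTrack, fit: MovementModelFit,
                grid_resolution_km: float = 1.0, levels=(0.5, 0.95),
                check_refinement: bool = True) -> UDResult:
    """Kernel utilization distribution with autocorrelation-aware bandwidth.

    Reference bandwidth H = Sigma_hat * N_eff^(-1/3); contour polygons are
    traced at the density threshold enclosing each probability level.  If
    halving the grid resolution changes the largest contour area by more
    than 5 % a warning suggests a finer resolution.
    """
    proj = AzimuthalEqualArea(float(np.mean(track.lon)), float(np.mean(track.lat)))
    x, y = proj.forward(track.lon, track.lat)
    pts = np.column_stack([x, y])
    Sigma = np.cov(pts.T)
    n_eff = fit.n_eff()
    H = Sigma * n_eff ** (-1.0 / 3.0)

    def compute(res):
        pad = 3.0 * np.sqrt(np.max(np.linalg.eigvalsh(H)))
        x_cent = np.arange(pts[:, 0].min() - pad, pts[:, 0].max() + pad + res, res)
        y_cent = np.arange(pts[:, 1].min() - pad, pts[:, 1].max() + pad + res, res)
        dens = _kde_mass(pts, H, x_cent, y_cent)
        mass = dens * res * res
        mass = mass / mass.sum()
        return x_cent, y_cent, mass

    x_cent, y_cent, mass = compute(grid_resolution_km)
    cell_area = grid_resolution_km ** 2
    ud = UDResult(proj=proj, x_edges=x_cent, y_edges=y_cent, density=mass,
                  cell_area_km2=cell_area, n_eff=n_eff)
    for level in levels:
        thr = _hdr_threshold(mass, level)
        polys_km, polys = _contour_polygons(mass, x_cent, y_cent, thr, proj)
        area = float((mass >= thr).sum()) * cell_area
        ud.contours[level] = {"threshold": thr, "polygons": polys,
                              "polygons_km": polys_km, "area_km2": area}
    if check_refinement:
        res2 = grid_resolution_km / 2.0
        _, _, mass2 = compute(res2)
        lvl = max(levels)
        a1 = ud.contours[lvl]["area_km2"]
        a2 = float((mass2 >= _hdr_threshold(mass2, lvl)).sum()) * res2 ** 2
        if a1 > 0 and abs(a2 - a1) / a1 > 0.05:
            warnings.warn(
                f"UD grid too coarse: {max(levels):.0%} contour area changes "
                f"{abs(a2 - a1) / a1:.1%} on refinement; consider resolution "
                f"{res2:g} km")
    return ud


def core_and_homerange(ud: UDResult):
    """The 50 % (core) and 95 % (home-range) contour polygon sets."""
    return ud.contours[0.5], ud.contours[0.95]
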