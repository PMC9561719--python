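"""GPS-track handling, variograms, OU movement models and residency.

A range-resident animal's positions are modelled as a two-dimensional
Ornstein–Uhlenbeck (OU) process: attraction to a home-range centre μ with
stationary variance σ² per axis and a position-autocorrelation timescale
τ (days) — the characteristic home-range crossing time.  The exact discrete
transition

    x(t+Δ) = μ + e^(−Δ/τ) (x(t) − μ) + ε,   ε ~ N(0, σ² (1 − e^(−2Δ/τ)))

holds for any Δ, so irregular sampling needs no interpolation.  The
effective sample size for area estimation, DOF_area = sampling span / τ,
counts home-range crossings; tracks with DOF_area > 5 — or a semi-variogram
that levels off — are classified range-resident, the precondition for
home-range estimation downstream.

Coordinates are converted once per individual from lon/lat to a local
azimuthal-equidistant frame in km; the conversion is explicit and invertible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .grid import EARTH_RADIUS_KM

__all__ = [
    "Track",
    "Variogram",
    "MovementFit",
    "ResidencyStatus",
    "InsufficientDataError",
    "lonlat_to_local_km",
    "local_km_to_lonlat",
    "read_tracks",
    "clean_track",
    "empirical_variogram",
    "fit_ou",
    "profile_interval",
    "classify_residency",
]

logger = logging.getLogger(__name__)

#: Movebank-style CSV dialect defaults.
DEFAULT_TRACK_COLUMNS = {
    "id": "individual-local-identifier",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
}


class InsufficientDataError(ValueError):
    """Fewer than two usable relocations after cleaning."""


# ---------------------------------------------------------------------------
# local metric frame (azimuthal equidistant on the sphere)
# ---------------------------------------------------------------------------

def lonlat_to_local_km(
    lons: np.ndarray, lats: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat to km in an azimuthal-equidistant frame at (lon0, lat0)."""
    lam = np.deg2rad(np.asarray(lons, dtype=float) - lon0)
    phi = np.deg2rad(np.asarray(lats, dtype=float))
    phi0 = math.radians(lat0)
    cos_c = np.clip(
        math.sin(phi0) * np.sin(phi) + math.cos(phi0) * np.cos(phi) * np.cos(lam),
        -1.0, 1.0,
    )
    c = np.arccos(cos_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 0, c / np.sin(np.where(c > 0, c, 1.0)), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam)
    y = EARTH_RADIUS_KM * k * (
        math.cos(phi0) * np.sin(phi) - math.sin(phi0) * np.cos(phi) * np.cos(lam)
    )
    return x, y


def local_km_to_lonlat(
    x: np.ndarray, y: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`lonlat_to_local_km`."""
    x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
    y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
    c = np.hypot(x, y)
    phi0 = math.radians(lat0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_c = np.sin(c)
        cos_c = np.cos(c)
        safe_c = np.where(c > 0, c, 1.0)
        phi = np.arcsin(
            np.where(
                c > 0,
                cos_c * math.sin(phi0) + y * sin_c * math.cos(phi0) / safe_c,
                math.sin(phi0),
            )
        )
        lam = np.where(
            c > 0,
            np.arctan2(
                x * sin_c,
                safe_c * math.cos(phi0) * cos_c - y * math.sin(phi0) * sin_c,
            ),
            0.0,
        )
    return lon0 + np.rad2deg(lam), np.rad2deg(phi)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """Cleaned, time-ordered relocations of one individual.

    ``times`` are days since the first fix; ``x``/``y`` km in a local
    azimuthal-equidistant frame centred on (``lon0``, ``lat0``); the
    original lon/lat are retained for gridding.
    """

    individual: str
    times: np.ndarray  # days, strictly increasing, starts at 0
    x: np.ndarray      # km
    y: np.ndarray      # km
    lon0: float
    lat0: float
    lons: np.ndarray | None = None
    lats: np.ndarray | None = None
    n_removed: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.times) < 2:
            raise InsufficientDataError("a track needs at least two relocations")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("track times must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def span_days(self) -> float:
        return float(self.times[-1] - self.times[0])


def read_tracks(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Split a Movebank-like CSV into one raw relocation frame per individual."""
    cols = dict(DEFAULT_TRACK_COLUMNS)
    if column_map:
        cols.update(column_map)
    frame = pd.read_csv(path)
    for key in ("id", "timestamp", "lon", "lat"):
        if cols[key] not in frame.columns:
            raise ValueError(f"missing mandatory column {cols[key]!r} in {path}")
    out: dict[str, pd.DataFrame] = {}
    for ident, sub in frame.groupby(cols["id"], sort=True):
        out[str(ident)] = sub.reset_index(drop=True)
    return out


def clean_track(
    raw: pd.DataFrame,
    individual: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> Track:
    """Sort by time, collapse duplicate timestamps (first kept), project to km.

    The local frame origin is the mean relocation; removals are counted on
    the returned track and logged.
    """
    cols = dict(DEFAULT_TRACK_COLUMNS)
    if column_map:
        cols.update(column_map)
    ident = individual or (
        str(raw[cols["id"]].iloc[0]) if cols["id"] in raw.columns else "unknown"
    )
    when = pd.to_datetime(raw[cols["timestamp"]], errors="coerce", format="mixed")
    lon = pd.to_numeric(raw[cols["lon"]], errors="coerce")
    lat = pd.to_numeric(raw[cols["lat"]], errors="coerce")
    ok = when.notna() & lon.notna() & lat.notna()
    sub = pd.DataFrame({"t": when[ok], "lon": lon[ok], "lat": lat[ok]})
    n_bad = int((~ok).sum())
    sub = sub.sort_values("t", kind="stable")
    before = len(sub)
    sub = sub.drop_duplicates(subset="t", keep="first")
    n_dup = before - len(sub)
    if len(sub) < 2:
        raise InsufficientDataError(f"track {ident!r}: fewer than two usable relocations")
    if n_bad or n_dup:
        logger.info("track %s: dropped %d unparseable and %d duplicate rows", ident, n_bad, n_dup)
    t0 = sub.t.iloc[0]
    times = (sub.t - t0).dt.total_seconds().to_numpy() / 86400.0
    lon0 = float(sub.lon.mean())
    lat0 = float(sub.lat.mean())
    x, y = lonlat_to_local_km(sub.lon.to_numpy(), sub.lat.to_numpy(), lon0, lat0)
    return Track(
        ident, times, x, y, lon0, lat0,
        lons=sub.lon.to_numpy(), lats=sub.lat.to_numpy(),
        n_removed=n_bad + n_dup,
    )


# ---------------------------------------------------------------------------
# variogram
# ---------------------------------------------------------------------------

@dataclass
class Variogram:
    """Semivariance of displacements per time-lag bin.

    γ(ℓ) = mean over pairs with lag in the bin of ‖Δr‖² / (2·dims), so for a
    range-resident OU track γ(ℓ) → σ² (the per-axis spatial variance) as
    ℓ → ∞, following γ(ℓ) = σ² (1 − e^(−ℓ/τ)).
    """

    lag_centers: np.ndarray   # days
    semivariance: np.ndarray  # km²
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        keep = self.pair_counts > 0
        self.lag_centers = np.asarray(self.lag_centers, dtype=float)[keep]
        self.semivariance = np.asarray(self.semivariance, dtype=float)[keep]
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)[keep]


def empirical_variogram(
    track: Track,
    n_bins: int = 30,
    max_lag: float | None = None,
    bin_edges: Sequence[float] | None = None,
    dims: int = 2,
) -> Variogram:
    """All-pairs empirical semi-variogram of a cleaned track.

    Bins are uniform on [0, max_lag] (default max_lag = half the span, the
    usual variogram rule of thumb) unless explicit ``bin_edges`` are given.
    ``dims`` is the normalisation in γ = mean‖Δr‖²/(2·dims); pass 1 for a
    deliberately one-dimensional track.
    """
    t, x, y = track.times, track.x, track.y
    if bin_edges is not None:
        edges = np.asarray(bin_edges, dtype=float)
    else:
        if max_lag is None:
            max_lag = track.span_days / 2.0
        if max_lag <= 0:
            raise ValueError("max_lag must be positive")
        edges = np.linspace(0.0, max_lag, n_bins + 1)
        edges[0] = np.nextafter(0.0, 1.0)  # exclude zero-lag self pairs
    n_b = len(edges) - 1
    sums = np.zeros(n_b)
    counts = np.zeros(n_b, dtype=int)
    n = track.n
    for i in range(n - 1):
        lags = t[i + 1:] - t[i]
        sq = (x[i + 1:] - x[i]) ** 2 + (y[i + 1:] - y[i]) ** 2
        idx = np.searchsorted(edges, lags, side="right") - 1
        ok = (idx >= 0) & (idx < n_b)
        if ok.any():
            np.add.at(sums, idx[ok], sq[ok])
            np.add.at(counts, idx[ok], 1)
    if not counts.any():
        raise ValueError("no displacement pairs fall in any lag bin")
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / np.maximum(counts, 1) / (2 * dims), 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Variogram(centers, gamma, counts)


# ---------------------------------------------------------------------------
# OU maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class MovementFit:
    """Maximum-likelihood OU fit for one track."""

    individual: str
    mu: tuple[float, float]        # km in the track's local frame
    sigma2: float                  # km² per axis, stationary variance
    tau_days: float                # position autocorrelation timescale
    log_likelihood: float
    dof_area: float                # span / tau: effective range crossings
    span_days: float
    flagged: bool = False          # tau hit an optimizer bound
    lon0: float = 0.0
    lat0: float = 0.0

    @property
    def mu_lonlat(self) -> tuple[float, float]:
        lon, lat = local_km_to_lonlat(
            np.array([self.mu[0]]), np.array([self.mu[1]]), self.lon0, self.lat0
        )
        return float(lon[0]), float(lat[0])


def _ou_profile(
    track: Track,
    tau: float,
    sigma2: float | None = None,
    reml: bool = True,
) -> tuple[float, float, float, float]:
    """Profile (restricted) likelihood at fixed τ.

    Returns (loglik, mu_x, mu_y, sigma2).  μ (and, when not fixed, σ²) have
    closed-form maximisers given τ; the first observation enters with its
    stationary distribution N(μ, σ²).  With ``reml`` (the default) the mean
    is integrated out rather than plugged in, which removes the downward
    bias in σ̂² and τ̂ that plain ML incurs on strongly autocorrelated
    tracks where μ itself must be estimated.
    """
    dt = np.diff(track.times)
    rho = np.exp(-dt / tau)
    a = np.concatenate(([1.0], 1.0 - rho))        # coefficient of μ
    v = np.concatenate(([1.0], 1.0 - rho**2))     # variance / σ²
    denom = float(np.sum(a * a / v))              # per-axis μ information / σ²
    n = track.n
    mus = []
    rss = 0.0
    for z in (track.x, track.y):
        yv = np.concatenate(([z[0]], z[1:] - rho * z[:-1]))
        mu = float(np.sum(a * yv / v)) / denom
        mus.append(mu)
        rss += float(np.sum((yv - a * mu) ** 2 / v))
    n_eff = 2 * (n - 1) if reml else 2 * n        # total Gaussian terms
    if sigma2 is None:
        sigma2 = rss / n_eff
    if sigma2 <= 0:
        return -math.inf, mus[0], mus[1], 0.0
    loglik = -0.5 * (
        n_eff * math.log(2 * math.pi * sigma2)
        + 2 * float(np.sum(np.log(v)))
        + rss / sigma2
    )
    if reml:
        loglik -= math.log(denom)                 # one ½·log per axis
    return loglik, mus[0], mus[1], sigma2


def fit_ou(track: Track, method: Literal["reml", "ml"] = "reml") -> MovementFit:
    """Fit the isotropic OU model (μ, σ², τ) by profile likelihood.

    Restricted likelihood (``reml``, default) integrates the unknown home
    range centre out of the variance estimation; plain ``ml`` is available
    for comparison.  τ is optimised on a log scale between a small fraction
    of the shortest sampling interval and many multiples of the span; a τ̂
    within 1% of either bound flags the fit (white-noise or drift-like
    limits).
    """
    if track.span_days <= 0:
        raise InsufficientDataError("track has zero sampling span")
    reml = method == "reml"
    dt = np.diff(track.times)
    tau_lo = max(float(dt.min()) * 1e-3, 1e-8)
    tau_hi = track.span_days * 100.0
    res = minimize_scalar(
        lambda log_tau: -_ou_profile(track, math.exp(log_tau), reml=reml)[0],
        bounds=(math.log(tau_lo), math.log(tau_hi)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    tau = math.exp(res.x)
    loglik, mu_x, mu_y, sigma2 = _ou_profile(track, tau, reml=reml)
    # τ below half the shortest sampling interval is unresolvable
    # (white-noise limit); τ at the upper bound indicates drift/dispersal
    flagged = (
        not math.isfinite(loglik)
        or tau <= float(dt.min()) * 0.5
        or tau >= tau_hi * 0.99
        or sigma2 <= 0
    )
    return MovementFit(
        individual=track.individual,
        mu=(mu_x, mu_y),
        sigma2=sigma2,
        tau_days=tau,
        log_likelihood=loglik,
        dof_area=track.span_days / tau,
        span_days=track.span_days,
        flagged=flagged,
        lon0=track.lon0,
        lat0=track.lat0,
    )


def profile_interval(
    track: Track,
    fit: MovementFit,
    param: str,
    level: float = 0.95,
) -> tuple[float, float]:
    """Likelihood-ratio confidence interval for ``param`` ("tau" or "sigma2").

    The profile log-likelihood is scanned away from the MLE until it drops
    by χ²₁(level)/2; the crossing is refined by bisection.  Bounds that never
    cross within a wide scan are reported as the scan limits.
    """
    from scipy.optimize import brentq
    from scipy.stats import chi2

    drop = 0.5 * chi2.ppf(level, df=1)
    ll_max = fit.log_likelihood

    if param == "tau":
        def pll(value: float) -> float:
            return _ou_profile(track, value)[0]
        mle = fit.tau_days
    elif param == "sigma2":
        def pll(value: float) -> float:
            res = minimize_scalar(
                lambda lt: -_ou_profile(track, math.exp(lt), value)[0],
                bounds=(math.log(fit.tau_days) - 6.0, math.log(fit.tau_days) + 6.0),
                method="bounded",
            )
            return -res.fun
        mle = fit.sigma2
    else:
        raise ValueError("param must be 'tau' or 'sigma2'")

    def crossing(sign: int) -> float:
        lo, hi = mle, mle
        factor = 1.25 if sign > 0 else 0.8
        for _ in range(60):
            hi = hi * factor
            if pll(hi) < ll_max - drop:
                f = lambda v: pll(v) - (ll_max - drop)
                return brentq(f, min(lo, hi), max(lo, hi), xtol=1e-9 * mle)
            lo = hi
        return hi  # never crossed inside the scan

    return crossing(-1), crossing(+1)


# ---------------------------------------------------------------------------
# residency
# ---------------------------------------------------------------------------

@dataclass
class ResidencyStatus:
    verdict: str                   # "resident" | "non-resident"
    dof_rule: bool                 # DOF_area > threshold
    asymptote_rule: bool           # variogram levelled off
    manual_override: bool | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def resident(self) -> bool:
        return self.verdict == "resident"


def _variogram_asymptote(
    variogram: Variogram, asymptote_fraction: float
) -> tuple[bool, dict]:
    """Saturating-curve asymptote test.

    The empirical semi-variogram is fitted (pair-count weighted) with the
    saturating model γ(ℓ) = s·(1 − e^(−ℓ/t)).  The track has "obtained an
    asymptote" when the fitted range t̂ lies well inside the sampled lags:
    t̂ < asymptote_fraction × max lag (default 1/6, i.e. the curve is ≥95%
    saturated by half the maximum lag).  A flat-zero variogram (no
    movement) trivially passes; an unbounded, drift-like variogram drives
    t̂ to the window scale or beyond and fails.
    """
    from scipy.optimize import curve_fit

    lags = variogram.lag_centers
    gam = variogram.semivariance
    if len(lags) < 4:
        return False, {"reason": "too few lag bins for the asymptote fit"}
    plateau = float(np.mean(gam[-max(3, len(gam) // 3):]))
    if plateau == 0:
        return True, {"plateau": 0.0, "fitted_range_days": 0.0}
    max_lag = float(lags[-1])
    try:
        popt, _ = curve_fit(
            lambda l, s, t: s * (1.0 - np.exp(-l / t)),
            lags, gam,
            p0=[plateau, max_lag / 10.0],
            sigma=1.0 / np.sqrt(variogram.pair_counts),
            bounds=([0.0, 1e-9], [np.inf, 1e9]),
            maxfev=5000,
        )
        t_hat = float(popt[1])
    except RuntimeError:
        return False, {"reason": "asymptote fit did not converge"}
    return t_hat < asymptote_fraction * max_lag, {
        "plateau": plateau,
        "fitted_sill_km2": float(popt[0]),
        "fitted_range_days": t_hat,
        "max_lag_days": max_lag,
    }


def classify_residency(
    fit: MovementFit,
    variogram: Variogram,
    dof_threshold: float = 5.0,
    asymptote_fraction: float = 1.0 / 6.0,
    manual_override: bool | None = None,
) -> ResidencyStatus:
    """Resident iff DOF_area exceeds the threshold OR the variogram levels off.

    ``manual_override`` stands in for the expert judgement of whether the
    animal inhabited its range during monitoring; when given it decides.
    """
    dof_rule = fit.dof_area > dof_threshold and not fit.flagged
    asym_rule, diag = _variogram_asymptote(variogram, asymptote_fraction)
    if manual_override is not None:
        verdict = "resident" if manual_override else "non-resident"
    else:
        verdict = "resident" if (dof_rule or asym_rule) else "non-resident"
    diag["dof_area"] = fit.dof_area
    return ResidencyStatus(verdict, dof_rule, asym_rule, manual_override, diag)
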