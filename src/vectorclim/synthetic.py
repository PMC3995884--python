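"""Seeded synthetic stations, LST cubes and rainfall with known truth.

Every generator is a pure function of a :class:`SynthConfig`; the returned
truth records carry the generating parameters so that tests can compare
estimates against them. Default conditions emulate a Madagascar-scale
problem: 26 stations over an island-sized bounding box, 30 years of daily
anomalies drawn from a Gaussian random field with sill 4 °C² and
half-correlation distance 150 km, a central-plateau altitude model, an
altitude-dependent dew point (−6 °C/km), AR(1) satellite-LST departures,
cloud-blob missingness and intermittent gamma-distributed rainfall.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geostat import covariance_model, pairwise_distances_km
from .station_io import StationSeries
from .lst_completion import GridTimeSeries
from ._dates import day_of_year_365


@dataclass
class SynthConfig:
    """Generating parameters for all three synthetic sources."""

    seed: int = 0
    # region & network
    n_stations: int = 26
    lat_range: tuple = (-25.5, -12.0)
    lon_range: tuple = (43.2, 50.5)
    start: str = "1981-01-01"
    n_years: int = 30
    # altitude model: central plateau with linear flanks
    plateau_height_m: float = 1400.0
    plateau_halfwidth_deg: float = 2.5
    # spatial anomaly field (Gaussian, independent across days)
    sill: float = 4.0  # °C²
    half_dist_km: float = 150.0
    nugget: float = 0.0
    # seasonal truth (°C): mean at sea level and k=1..3 cosine amplitudes
    seasonal_mean: float = 22.0
    seasonal_cos: tuple = (4.0, 0.5, 0.0)
    seasonal_sin: tuple = (1.0, 0.0, 0.0)
    lapse_rate: float = -0.006  # °C per metre
    missing_rate: float = 0.1
    # LST cube
    lst_shape: tuple = (20, 20)
    lst_years: int = 3
    lst_phi: float = 0.7  # AR(1) coefficient of the departures
    lst_std: float = 1.8  # base departure std, °C
    lst_mean_sea: float = 30.0
    lst_missing_rate: float = 0.15
    lst_blob_prob: float = 0.7
    lst_blobs_per_day: tuple = (1, 4)
    lst_blob_radius_px: tuple = (2.0, 6.0)
    # rainfall (coarse grid)
    rain_shape: tuple = (8, 8)
    rain_days: int = 3650
    wet_prob: float = 0.3
    wet_persistence: float = 0.5
    spatial_mixing: float = 0.5  # shared-forcing weight (Gaussian copula)
    gamma_shape: float = 0.8
    gamma_scale: float = 12.0
    rain_missing_frac: float = 0.01
    extreme_prob: float = 2e-4  # injects values above the 300 mm/day cap


def altitude_model(lats, lons, cfg: SynthConfig) -> np.ndarray:
    """Deterministic plateau-and-slope altitude (m) as a function of location."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    lon_c = 0.5 * (cfg.lon_range[0] + cfg.lon_range[1])
    plateau = np.clip(1.0 - np.abs(lons - lon_c) / cfg.plateau_halfwidth_deg, 0.0, 1.0)
    slope = 0.1 * (lats - cfg.lat_range[0]) / (cfg.lat_range[1] - cfg.lat_range[0])
    return cfg.plateau_height_m * plateau * (1.0 + slope)


def _seasonal_curve(t_days, cfg: SynthConfig) -> np.ndarray:
    out = np.full(len(t_days), cfg.seasonal_mean, dtype=float)
    for k in range(1, 4):
        w = 2.0 * np.pi * k / 365.25
        out += cfg.seasonal_cos[k - 1] * np.cos(w * t_days)
        out += cfg.seasonal_sin[k - 1] * np.sin(w * t_days)
    return out


def gen_station_network(cfg: SynthConfig):
    """Synthetic daily station network with spatially correlated anomalies.

    Values are seasonal truth + lapse·altitude + a zero-mean Gaussian
    anomaly field with covariance C(d) = sill·2^(−d/λ), independent across
    days; a fraction of measurements is deleted at random.

    Returns (stations, truth) where truth records every generating
    parameter plus the complete anomaly matrix.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_stations
    if n < 2:
        raise ValueError("need at least 2 stations")
    lats = rng.uniform(*cfg.lat_range, size=n)
    lons = rng.uniform(*cfg.lon_range, size=n)
    alts = altitude_model(lats, lons, cfg)

    n_days = int(round(cfg.n_years * 365.25))
    dates = pd.date_range(cfg.start, periods=n_days, freq="D").to_numpy(
        dtype="datetime64[D]"
    )
    t = dates.astype("datetime64[D]").astype(float)

    D = pairwise_distances_km(lats, lons)
    C = covariance_model(D, cfg.sill, cfg.half_dist_km, cfg.nugget)
    np.fill_diagonal(C, cfg.sill)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * cfg.sill
        L = np.linalg.cholesky(C + jitter * np.eye(n))
    anomalies = L @ rng.standard_normal((n, n_days))

    seasonal = _seasonal_curve(t, cfg)
    valid = rng.random((n, n_days)) >= cfg.missing_rate

    stations = []
    for i in range(n):
        vals = seasonal + cfg.lapse_rate * alts[i] + anomalies[i]
        vals = np.where(valid[i], vals, np.nan)
        stations.append(StationSeries(
            station_id=f"SYN{i:03d}", lat=float(lats[i]), lon=float(lons[i]),
            altitude=float(alts[i]), dates=dates, values=vals, valid=valid[i],
        ))
    truth = {
        "config": asdict(cfg), "lats": lats, "lons": lons, "altitudes": alts,
        "anomalies": anomalies, "valid": valid, "dates": dates,
        "seasonal": seasonal,
    }
    return stations, truth


def _ellipse_mask(ny, nx, cy, cx, ay, ax_, theta):
    yy, xx = np.mgrid[0:ny, 0:nx]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    return (u / ax_) ** 2 + (v / ay) ** 2 <= 1.0


def gen_lst_cube(cfg: SynthConfig):
    """Synthetic daily LST cube with AR(1) departures and cloud-blob gaps.

    Returns (grid, truth_values) where ``grid`` is a GridTimeSeries with
    missing values masked out and ``truth_values`` is the complete cube.
    """
    ny, nx = cfg.lst_shape
    if ny > 100 or nx > 100:
        raise ValueError("desk-scale cubes are limited to 100x100 pixels")
    rng = np.random.default_rng(cfg.seed + 1)
    lats = np.linspace(cfg.lat_range[0], cfg.lat_range[1], ny)
    lons = np.linspace(cfg.lon_range[0], cfg.lon_range[1], nx)
    LA, LO = np.meshgrid(lats, lons, indexing="ij")
    alt = altitude_model(LA, LO, cfg)

    n_days = int(round(cfg.lst_years * 365.25))
    dates = pd.date_range("2003-01-01", periods=n_days, freq="D").to_numpy(
        dtype="datetime64[D]"
    )
    t = dates.astype(float)
    doys = day_of_year_365(dates)

    mean_pix = cfg.lst_mean_sea - 0.0065 * alt  # (ny, nx)
    w1 = 2.0 * np.pi / 365.25
    seasonal = 3.0 * np.cos(w1 * t)[:, None, None] + 0.8 * np.sin(w1 * t)[:, None, None]
    # mild day-of-year modulation of the departure scale
    sigma_pix = cfg.lst_std * (1.0 + alt / 8000.0)
    sigma_doy = 1.0 + 0.15 * np.cos(2.0 * np.pi * doys / 365.0)

    phi = cfg.lst_phi
    eps = rng.standard_normal((n_days, ny, nx)) * np.sqrt(1.0 - phi ** 2)
    x = np.empty((n_days, ny, nx))
    x[0] = rng.standard_normal((ny, nx))
    for k in range(1, n_days):
        x[k] = phi * x[k - 1] + eps[k]

    truth_values = (mean_pix[None] + seasonal
                    + sigma_pix[None] * sigma_doy[:, None, None] * x)

    valid = rng.random((n_days, ny, nx)) >= cfg.lst_missing_rate
    lo, hi = cfg.lst_blobs_per_day
    rlo, rhi = cfg.lst_blob_radius_px
    for k in range(n_days):
        if rng.random() >= cfg.lst_blob_prob:
            continue
        for _ in range(rng.integers(lo, hi + 1)):
            mask = _ellipse_mask(
                ny, nx,
                cy=rng.uniform(0, ny - 1), cx=rng.uniform(0, nx - 1),
                ay=rng.uniform(rlo, rhi), ax_=rng.uniform(rlo, rhi),
                theta=rng.uniform(0, np.pi),
            )
            valid[k][mask] = False

    values = np.where(valid, truth_values, np.nan)
    grid = GridTimeSeries(dates=dates, values=values, valid=valid,
                          lats=lats, lons=lons)
    return grid, truth_values


def gen_rainfall(cfg: SynthConfig):
    """Synthetic coarse daily rainfall with wet/dry persistence.

    A two-state Markov chain per cell (stationary wet fraction =
    ``wet_prob``, persistence ``wet_persistence``) is driven through a
    Gaussian copula by a shared daily forcing, giving spatially correlated
    wet days. Wet amounts are gamma distributed; a small fraction of cells
    is set missing (NaN) and occasional extremes above 300 mm/day are
    injected to exercise the preprocessing cap.

    Returns (raw, lats, lons, dates, truth): ``raw`` is the coarse cube
    with NaN where missing.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    ny, nx = cfg.rain_shape
    nt = cfg.rain_days
    lats = np.linspace(cfg.lat_range[0], cfg.lat_range[1], ny)
    lons = np.linspace(cfg.lon_range[0], cfg.lon_range[1], nx)
    dates = pd.date_range("2001-01-01", periods=nt, freq="D").to_numpy(
        dtype="datetime64[D]"
    )

    pi = cfg.wet_prob
    rho = cfg.wet_persistence
    p01 = (1.0 - rho) * pi  # dry -> wet
    p11 = rho + (1.0 - rho) * pi  # wet -> wet

    from scipy.stats import norm
    c = cfg.spatial_mixing
    shared = rng.standard_normal(nt)
    local = rng.standard_normal((nt, ny, nx))
    u = norm.cdf(np.sqrt(c) * shared[:, None, None] + np.sqrt(1.0 - c) * local)

    wet = np.empty((nt, ny, nx), dtype=bool)
    wet[0] = u[0] < pi
    for k in range(1, nt):
        p = np.where(wet[k - 1], p11, p01)
        wet[k] = u[k] < p

    amounts = rng.gamma(cfg.gamma_shape, cfg.gamma_scale, size=(nt, ny, nx))
    raw = np.where(wet, amounts, 0.0)
    extreme = rng.random((nt, ny, nx)) < cfg.extreme_prob
    raw = np.where(extreme, rng.uniform(305.0, 400.0, size=raw.shape), raw)
    missing = rng.random((nt, ny, nx)) < cfg.rain_missing_frac
    raw = np.where(missing, np.nan, raw)

    truth = {
        "config": asdict(cfg), "wet": wet, "missing": missing,
        "extreme": extreme, "p01": p01, "p11": p11,
    }
    return raw, lats, lons, dates, truth
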