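"""Daily climate-normal surfaces and day-of-year lapse rates.

Monthly climate normals (WorldClim-style) are turned into daily normals by
fitting, per pixel, the constant + 1,2,3 cycles/year harmonic basis to the
12 monthly values anchored at mid-month days-of-year and evaluating the
fitted curve daily. Dew point has no such high-resolution normal, so a
region-wide day-of-year lapse rate (°C per meter of altitude) is regressed
from pooled (altitude, dew point) pairs and smoothed along the year; it
converts measurements to zero-altitude equivalents and back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from ._dates import N_DOY
from .harmonics import harmonic_design
from .geostat import median_mean_smooth

#: Mid-month anchor days-of-year for the 12 monthly normals.
MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])


class LapseRateWarning(UserWarning):
    """Altitude range too narrow for a reliable lapse-rate estimate."""


@dataclass
class DailyClimate:
    """Daily-resolution climate normal: (365, nlat, nlon) value cube."""

    lats: np.ndarray
    lons: np.ndarray
    normal: np.ndarray  # (365, nlat, nlon)

    def __post_init__(self):
        self.normal = np.asarray(self.normal, dtype=float)
        if self.normal.shape[0] != N_DOY:
            raise ValueError(f"normal must have {N_DOY} leading entries")

    def for_doy(self, doy: int) -> np.ndarray:
        return self.normal[int(doy) - 1]


def daily_from_monthly(monthly, lats=None, lons=None) -> DailyClimate:
    """Interpolate 12 monthly normal surfaces to 365 daily surfaces.

    Per pixel, the 7-parameter harmonic basis is least-squares fitted to the
    12 monthly values at mid-month anchors and evaluated for every
    day-of-year. Pixels with any non-finite month are masked (NaN) in the
    output.
    """
    monthly = np.asarray(monthly, dtype=float)
    if monthly.shape[0] != 12:
        raise ValueError("monthly must be a (12, ...) stack")
    spatial_shape = monthly.shape[1:]
    flat = monthly.reshape(12, -1)

    B12 = harmonic_design(MID_MONTH_DOY.astype(float))
    B365 = harmonic_design(np.arange(1, N_DOY + 1, dtype=float))
    pinv = np.linalg.pinv(B12)

    ok = np.all(np.isfinite(flat), axis=0)
    coef = np.full((B12.shape[1], flat.shape[1]), np.nan)
    coef[:, ok] = pinv @ flat[:, ok]
    daily = (B365 @ coef).reshape((N_DOY,) + spatial_shape)
    daily[:, ~ok.reshape(spatial_shape)] = np.nan

    if lats is None:
        lats = np.arange(spatial_shape[0]) if spatial_shape else np.array([0.0])
    if lons is None:
        lons = np.arange(spatial_shape[-1]) if spatial_shape else np.array([0.0])
    return DailyClimate(lats=np.asarray(lats), lons=np.asarray(lons), normal=daily)


@dataclass
class LapseDOY:
    """Day-of-year lapse rate (°C/m) with the standard error of each slope."""

    rate: np.ndarray  # length 365
    spread: np.ndarray  # length 365

    def __post_init__(self):
        self.rate = np.asarray(self.rate, dtype=float)
        self.spread = np.asarray(self.spread, dtype=float)
        if len(self.rate) != N_DOY or len(self.spread) != N_DOY:
            raise ValueError(f"rate/spread must have length {N_DOY}")

    def for_doy(self, doy: int) -> float:
        return float(self.rate[int(doy) - 1])


def _pooled_pairs(stations, doy: int):
    """All (altitude, value) pairs across years for one DOY."""
    alts, vals = [], []
    for s in stations:
        sel = (s.doy() == doy) & s.valid
        n = int(sel.sum())
        if n:
            alts.append(np.full(n, s.altitude))
            vals.append(s.values[sel])
    if not alts:
        return np.array([]), np.array([])
    return np.concatenate(alts), np.concatenate(vals)


def fit_lapse_rate(stations, doy: int):
    """OLS slope of value vs altitude pooled over all years for one DOY.

    Returns (rate, spread) where spread is the standard error of the slope.
    Requires measurements from at least 3 distinct altitudes; an altitude
    range under 100 m triggers a reliability warning but still returns.
    """
    alts, vals = _pooled_pairs(stations, doy)
    if len(np.unique(alts)) < 3:
        raise ValueError(
            f"DOY {doy}: need reporting stations at >= 3 distinct altitudes"
        )
    if np.ptp(alts) < 100.0:
        warnings.warn(
            f"DOY {doy}: altitude range {np.ptp(alts):.0f} m < 100 m; "
            "lapse rate may be unreliable",
            LapseRateWarning,
        )
    res = stats.linregress(alts, vals)
    return float(res.slope), float(res.stderr)


class LapseRateModel(RegressorMixin, BaseEstimator):
    """Day-of-year lapse-rate regression over a station network.

    ``fit`` regresses value on altitude for every DOY (pooled over years)
    and smooths the 365 slopes with the circular 31-day median-mean filter.

    Attributes
    ----------
    lapse_ : LapseDOY
        Smoothed rates and slope standard errors.
    raw_rate_ : ndarray
        Unsmoothed per-DOY slopes (NaN where the regression failed).
    """

    def __init__(self, window: int = 31):
        self.window = window

    def fit(self, stations, y=None):
        rate = np.full(N_DOY, np.nan)
        spread = np.full(N_DOY, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", LapseRateWarning)
            for d in range(1, N_DOY + 1):
                try:
                    rate[d - 1], spread[d - 1] = fit_lapse_rate(stations, d)
                except ValueError:
                    continue
        if np.all(np.isnan(rate)):
            raise ValueError("lapse-rate regression failed for every day-of-year")
        self.raw_rate_ = rate
        self.lapse_ = LapseDOY(
            rate=median_mean_smooth(rate, self.window),
            spread=median_mean_smooth(spread, self.window),
        )
        return self

    def predict(self, doys):
        return self.lapse_.rate[np.asarray(doys, dtype=int) - 1]


def fit_lapse_doy(stations, window: int = 31) -> LapseDOY:
    """Smoothed day-of-year lapse rates for a station network."""
    return LapseRateModel(window=window).fit(stations).lapse_


def altitude_adjust(values, altitudes, rate, direction: str):
    """Remove or restore the altitude effect using a lapse rate.

    ``remove`` maps a measurement to its zero-altitude equivalent
    (v₀ = v − rate·altitude); ``restore`` inverts it. The two directions
    compose to the identity.
    """
    values = np.asarray(values, dtype=float)
    altitudes = np.asarray(altitudes, dtype=float)
    if not np.all(np.isfinite(np.atleast_1d(rate))):
        raise ValueError("lapse rate must be finite")
    if direction == "remove":
        return values - rate * altitudes
    if direction == "restore":
        return values + rate * altitudes
    raise ValueError("direction must be 'remove' or 'restore'")
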