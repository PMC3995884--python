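"""Gap filling of daily land-surface-temperature (LST) grids.

Satellite LST products lose pixels to cloud and aerosol. Each pixel's daily
series is decomposed into a seasonal-harmonic curve (after stripping the
16-day orbital repeat-cycle noise), its anomalies are stationarized by the
day-of-year standard deviation measured in a 31-day window with weights
w(t) = 1 − |t/16|³, and outliers beyond four recomputed standard deviations
are removed iteratively. Missing values of the resulting unit-variance
departure series are estimated by simple Kriging *in time*, using a
per-pixel power-law autocorrelation model ρ(τ) = c·τ^(−α) fitted up to the
first negative empirical lag. The temporal guess G (with remaining variance
fraction E) is blended with the regional mean departure of the day, A_avg:

    z_est = (1 − E)·G + E·A_avg,     LST = MEAN + STD·z_est.

Pixels whose record is too sparse to support the seasonal fit (pathological:
DOY gap > 30 or fewer than 61 valid samples in every 365-day window) borrow
MEAN/STD from valid neighbours, iteratively, most-connected first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._dates import N_DOY, day_of_year_365, days_since_epoch
from .harmonics import (
    SeasonalFitError,
    SeasonalModel,
    fit_seasonal,
    remove_noise_harmonics,
)
from .station_io import MAX_DOY_GAP, MIN_WINDOW_COUNT, max_circular_gap

#: PixelClimatology.source codes
SOURCE_FITTED = 0
SOURCE_NEIGHBOR = 1
SOURCE_REGIONAL = 2

#: Weighted-window half width: weights w(t) = 1 - |t/16|^3 for |t| <= 15.
STD_WINDOW_HALF = 15

OUTLIER_THRESHOLD = 4.0


class DegeneratePixelError(ValueError):
    """Pixel series cannot support seasonal statistics (treat as pathological)."""


class PathologicalRegionError(RuntimeError):
    """A pathological region exceeds the configured completion diameter."""


@dataclass
class GridTimeSeries:
    """(time × lat × lon) value cube with validity mask."""

    dates: np.ndarray  # datetime64[D], strictly increasing
    values: np.ndarray  # (nt, ny, nx) °C
    valid: np.ndarray  # (nt, ny, nx) bool
    land_mask: np.ndarray = None  # (ny, nx) bool
    lats: np.ndarray = None
    lons: np.ndarray = None

    def __post_init__(self):
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have the same shape")
        if self.values.shape[0] != len(self.dates):
            raise ValueError("leading axis must match dates")
        if len(self.dates) > 1 and not np.all(np.diff(self.dates).astype(int) > 0):
            raise ValueError("dates must be strictly increasing")
        if self.land_mask is None:
            self.land_mask = np.ones(self.values.shape[1:], dtype=bool)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)

    @property
    def shape(self):
        return self.values.shape

    def doy(self) -> np.ndarray:
        return day_of_year_365(self.dates)


@dataclass
class PixelClimatology:
    """Per-pixel day-of-year MEAN and STD surfaces with provenance."""

    mean: np.ndarray  # (365, ny, nx)
    std: np.ndarray  # (365, ny, nx)
    source: np.ndarray  # (ny, nx) int: fitted | neighbor_completed | regional_fallback

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        self.source = np.asarray(self.source, dtype=int)


@dataclass
class ACFModel:
    """Power-law temporal autocorrelation ρ(τ) = coeff · τ^(−exponent)."""

    coeff: float
    exponent: float
    max_lag: int

    def rho(self, tau) -> np.ndarray:
        """ρ at integer lags ≥ 1; ρ(0) is 1 by definition (handled by callers)."""
        tau = np.asarray(tau, dtype=float)
        with np.errstate(divide="ignore"):
            r = self.coeff * np.maximum(tau, 1.0) ** (-self.exponent)
        return np.clip(r, -0.999, 0.999)


# ---------------------------------------------------------------------------
# per-pixel operations
# ---------------------------------------------------------------------------

def classify_pathological(dates, valid) -> bool:
    """True when a pixel record is too sparse for seasonal statistics.

    Same thresholds as the station quality filter, negated: circular DOY
    gap > 30, or fewer than 61 valid samples in every 365-day window.
    """
    dates = np.asarray(dates, dtype="datetime64[D]")
    valid = np.asarray(valid, dtype=bool)
    vdates = dates[valid]
    if len(vdates) == 0:
        return True
    counts = np.zeros(N_DOY, dtype=int)
    np.add.at(counts, day_of_year_365(vdates) - 1, 1)
    if max_circular_gap(counts) > MAX_DOY_GAP:
        return True
    days = vdates.astype(int)
    best = 0
    j = 0
    for i in range(len(days)):
        if j < i:
            j = i
        while j < len(days) and days[j] - days[i] < 365:
            j += 1
        best = max(best, j - i)
    return best < MIN_WINDOW_COUNT


def window_weights(half: int = STD_WINDOW_HALF) -> np.ndarray:
    """w(t) = 1 − |t/16|³ for t in [−half, half]."""
    t = np.arange(-half, half + 1, dtype=float)
    return 1.0 - np.abs(t / (half + 1)) ** 3


def doy_weighted_std(anomalies, doys, half: int = STD_WINDOW_HALF) -> np.ndarray:
    """Seasonally varying std: weighted over a 31-day circular DOY window.

    ``anomalies`` carries NaN at invalid samples; ``doys`` is the 1..365
    index per sample. Returns a length-365 array.
    """
    anomalies = np.asarray(anomalies, dtype=float)
    ok = np.isfinite(anomalies)
    a = anomalies[ok]
    d = np.asarray(doys)[ok] - 1
    s0 = np.zeros(N_DOY)
    s1 = np.zeros(N_DOY)
    s2 = np.zeros(N_DOY)
    np.add.at(s0, d, 1.0)
    np.add.at(s1, d, a)
    np.add.at(s2, d, a * a)
    w = window_weights(half)
    W = np.zeros(N_DOY)
    W1 = np.zeros(N_DOY)
    W2 = np.zeros(N_DOY)
    for off, wt in zip(range(-half, half + 1), w):
        W += wt * np.roll(s0, -off)
        W1 += wt * np.roll(s1, -off)
        W2 += wt * np.roll(s2, -off)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = W1 / W
        var = W2 / W - m * m
    return np.sqrt(np.clip(var, 0.0, None))


def pixel_seasonal_stats(dates, values, valid, *, repeat_period: float = 16.0,
                         spike_factor: float = 4.0):
    """Seasonal model + day-of-year std for one pixel's daily series.

    Noise harmonics are removed first; the seasonal model is then fitted on
    the denoised valid samples and the anomaly std measured in the weighted
    31-day circular DOY window. Degenerate pixels (zero std anywhere, or
    seasonal fit failure) raise DegeneratePixelError so the caller can fall
    back to neighbour completion.
    """
    try:
        denoised = remove_noise_harmonics(
            dates, values, valid, repeat_period=repeat_period,
            spike_factor=spike_factor,
        )
        model = fit_seasonal(dates, denoised)
    except SeasonalFitError as exc:
        raise DegeneratePixelError(str(exc)) from exc
    anom = denoised - model.evaluate(dates)
    doy_std = doy_weighted_std(anom, day_of_year_365(np.asarray(dates, "datetime64[D]")))
    if np.any(~np.isfinite(doy_std)) or np.any(doy_std <= 0):
        raise DegeneratePixelError("day-of-year std is zero or undefined")
    return model, doy_std


def normalize_departures(dates, values, model: SeasonalModel, doy_std,
                         valid=None) -> np.ndarray:
    """z[t] = (value − seasonal)/doy_std[doy(t)]; NaN at invalid samples."""
    values = np.asarray(values, dtype=float)
    if valid is not None:
        values = np.where(np.asarray(valid, dtype=bool), values, np.nan)
    doys = day_of_year_365(np.asarray(dates, "datetime64[D]"))
    return (values - model.evaluate(dates)) / np.asarray(doy_std)[doys - 1]


def outlier_loop(z, threshold: float = OUTLIER_THRESHOLD, max_iter: int = 100):
    """Iteratively remove values beyond ``threshold`` recomputed stds.

    Each pass recomputes the mean and std of the surviving values and marks
    values with |z − m| strictly greater than threshold·s invalid (NaN);
    stops when a pass removes nothing. Returns (cleaned, n_removed).
    """
    z = np.asarray(z, dtype=float).copy()
    if np.isfinite(z).sum() < 10:
        raise ValueError("need >= 10 valid samples for the outlier loop")
    removed = 0
    for _ in range(max_iter):
        m = np.nanmean(z)
        s = np.nanstd(z)
        bad = np.abs(z - m) > threshold * s
        bad &= np.isfinite(z)
        n = int(bad.sum())
        if n == 0:
            return z, removed
        z[bad] = np.nan
        removed += n
    raise RuntimeError(f"outlier loop did not converge in {max_iter} iterations")


def empirical_acf(z, times=None, max_scan: int = 90):
    """Empirical autocorrelation over valid same-pixel pairs, lags 1..max_scan.

    Returns (lags, rho, n_pairs). ``times`` defaults to the sample index
    (daily cadence).
    """
    z = np.asarray(z, dtype=float)
    if times is None:
        times = np.arange(len(z))
    times = np.asarray(times, dtype=int)
    # dense series over the time span
    span = times.max() - times.min() + 1
    dense = np.full(span, np.nan)
    dense[times - times.min()] = z
    ok = np.isfinite(dense)
    m = np.nanmean(dense)
    var = np.nanvar(dense)
    lags = np.arange(1, min(max_scan, span - 1) + 1)
    rho = np.full(len(lags), np.nan)
    n_pairs = np.zeros(len(lags), dtype=int)
    x = np.where(ok, dense - m, 0.0)
    for i, lag in enumerate(lags):
        both = ok[:-lag] & ok[lag:]
        n = int(both.sum())
        n_pairs[i] = n
        if n > 0 and var > 0:
            rho[i] = np.sum(x[:-lag][both] * x[lag:][both]) / (n * var)
    return lags, rho, n_pairs


def fit_acf(z, times=None, *, min_pairs: int = 50, max_scan: int = 90):
    """Fit ρ(τ) = c·τ^(−α) to the empirical autocorrelation.

    The fit uses lags 1..(first negative lag − 1). Returns None when there
    are fewer than ``min_pairs`` lag-1 pairs, ρ̂(1) is not positive, or the
    fit fails — in which case temporal Kriging is skipped and missing values
    keep full variance.
    """
    lags, rho, n_pairs = empirical_acf(z, times, max_scan=max_scan)
    if len(lags) == 0 or n_pairs[0] < min_pairs or not np.isfinite(rho[0]):
        return None
    if rho[0] <= 0:
        return None
    neg = np.where(~np.isfinite(rho) | (rho < 0))[0]
    max_lag = int(lags[neg[0]] - 1) if len(neg) else int(lags[-1])
    if max_lag < 1:
        return None
    sel = slice(0, max_lag)
    r = rho[sel]
    t = lags[sel].astype(float)
    keep = np.isfinite(r)
    if keep.sum() == 1:
        return ACFModel(coeff=float(min(r[0], 1.0)), exponent=1.0, max_lag=max_lag)
    # least squares on the linear scale; coeff = rho(1) must stay <= 1
    import warnings

    from scipy.optimize import OptimizeWarning, curve_fit

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                lambda tau, c, a: c * tau ** (-a),
                t[keep], r[keep], p0=[min(float(r[0]), 0.99), 1.0],
                bounds=([1e-6, 0.0], [1.0, 10.0]), maxfev=5000,
            )
    except (RuntimeError, ValueError):
        return None
    c, alpha = float(popt[0]), float(popt[1])
    if not np.isfinite(c) or not np.isfinite(alpha):
        return None
    return ACFModel(coeff=c, exponent=alpha, max_lag=max_lag)


def temporal_krige(z, times, t_missing, acf: ACFModel):
    """Simple Kriging in time of a unit-variance departure series.

    Donors are valid samples within ``acf.max_lag`` days of the missing
    time. Returns (G, E): the Kriging guess and the remaining variance
    fraction, E = 1 − c₀ᵀC⁻¹c₀ clamped to [0, 1]. With no donors, (0, 1).
    """
    z = np.asarray(z, dtype=float)
    times = np.asarray(times, dtype=int)
    ok = np.isfinite(z)
    lagdist = np.abs(times - int(t_missing))
    donors = ok & (lagdist >= 1) & (lagdist <= acf.max_lag)
    assert not np.any(ok & (lagdist == 0)), "donor at the missing time itself"
    if not donors.any():
        return 0.0, 1.0
    td = times[donors]
    zd = z[donors]
    C = acf.rho(np.abs(td[:, None] - td[None, :]).astype(float))
    np.fill_diagonal(C, 1.0)
    c0 = acf.rho(np.abs(td - int(t_missing)).astype(float))
    # a fitted power law need not be positive definite on integer lags;
    # a truncated pseudo-inverse (relative cutoff 1e-2) keeps the solve in
    # the well-determined eigenspace and the weights bounded
    w = np.linalg.pinv(C, rcond=1e-2, hermitian=True) @ c0
    G = float(w @ zd)
    E = float(np.clip(1.0 - c0 @ w, 0.0, 1.0))
    return G, E


def blend_and_restore(G, E, a_avg, mean, std):
    """Blend the temporal guess with the regional departure and rescale.

    z_est = (1 − E)·G + E·A_avg;  LST = MEAN + STD·z_est.
    """
    z_est = (1.0 - np.asarray(E)) * np.asarray(G) + np.asarray(E) * np.asarray(a_avg)
    return np.asarray(mean) + np.asarray(std) * z_est


# ---------------------------------------------------------------------------
# pathological-pixel completion
# ---------------------------------------------------------------------------

_EIGHT = ndimage.generate_binary_structure(2, 2)


def complete_pathological(clim: PixelClimatology, patho: np.ndarray,
                          land: np.ndarray = None, *, max_diameter: int = 3,
                          allow_regional_fallback: bool = True) -> PixelClimatology:
    """Fill pathological pixels' MEAN/STD from valid neighbours.

    Connected pathological regions (8-connectivity) no wider than
    ``max_diameter`` pixels are completed iteratively, one pixel at a time,
    always the pixel with the most valid 8-neighbours (row-major ties);
    completed pixels immediately become donors. Isolated islands take the
    nearest valid land pixel's vectors. Wider regions are filled with the
    regional land average and flagged, or raise PathologicalRegionError when
    the regional fallback is disabled.
    """
    patho = np.asarray(patho, dtype=bool).copy()
    land = np.ones_like(patho) if land is None else np.asarray(land, dtype=bool)
    mean = clim.mean.copy()
    std = clim.std.copy()
    source = clim.source.copy()
    valid = land & ~patho

    labels, n_regions = ndimage.label(patho & land, structure=_EIGHT)
    for r in range(1, n_regions + 1):
        ys, xs = np.nonzero(labels == r)
        diameter = int(max(np.ptp(ys), np.ptp(xs))) + 1
        if diameter > max_diameter:
            if not allow_regional_fallback:
                rows = (int(ys.min()), int(ys.max()))
                cols = (int(xs.min()), int(xs.max()))
                raise PathologicalRegionError(
                    f"pathological region {r} spans rows {rows}, cols {cols} "
                    f"({diameter} px > {max_diameter} px limit)"
                )
            if not valid.any():
                raise PathologicalRegionError("no valid land pixels for fallback")
            mean[:, ys, xs] = np.nanmean(mean[:, valid], axis=1)[:, None]
            std[:, ys, xs] = np.nanmean(std[:, valid], axis=1)[:, None]
            source[ys, xs] = SOURCE_REGIONAL
            patho[ys, xs] = False
            valid[ys, xs] = True

    # iterative neighbour completion, most-connected pixel first
    while patho.any():
        kernel = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
        n_valid_nb = ndimage.convolve(
            valid.astype(int), kernel, mode="constant", cval=0
        )
        candidates = patho & land
        counts = np.where(candidates, n_valid_nb, -1)
        best = counts.max()
        if best <= 0:
            # remaining pixels are islands: nearest valid land pixel, row-major ties
            if not valid.any():
                raise PathologicalRegionError("no valid land pixels to copy from")
            vy, vx = np.nonzero(valid)
            for y, x in zip(*np.nonzero(candidates)):
                d2 = (vy - y) ** 2 + (vx - x) ** 2
                k = int(np.argmin(d2))  # argmin takes the first (row-major) tie
                mean[:, y, x] = mean[:, vy[k], vx[k]]
                std[:, y, x] = std[:, vy[k], vx[k]]
                source[y, x] = SOURCE_NEIGHBOR
                patho[y, x] = False
                valid[y, x] = True
            break
        ys, xs = np.nonzero(counts == best)
        y, x = int(ys[0]), int(xs[0])
        y0, y1 = max(0, y - 1), min(patho.shape[0], y + 2)
        x0, x1 = max(0, x - 1), min(patho.shape[1], x + 2)
        nb = valid[y0:y1, x0:x1].copy()
        nb[y - y0, x - x0] = False
        mean[:, y, x] = mean[:, y0:y1, x0:x1][:, nb].mean(axis=1)
        std[:, y, x] = std[:, y0:y1, x0:x1][:, nb].mean(axis=1)
        source[y, x] = SOURCE_NEIGHBOR
        patho[y, x] = False
        valid[y, x] = True

    return PixelClimatology(mean=mean, std=std, source=source)


# ---------------------------------------------------------------------------
# full-grid pipeline
# ---------------------------------------------------------------------------

@dataclass
class FillResult:
    """Output of :func:`fill_grid`."""

    grid: GridTimeSeries  # completed cube
    provenance: np.ndarray  # (nt, ny, nx) uint8: 0 observed, 1 filled
    variance: np.ndarray  # (nt, ny, nx): E·STD² at filled values, 0 at observed
    climatology: PixelClimatology
    n_outliers: int = 0


PROV_OBSERVED = 0
PROV_FILLED = 1


def fill_grid(grid: GridTimeSeries, *, repeat_period: float = 16.0,
              spike_factor: float = 4.0, outlier_threshold: float = OUTLIER_THRESHOLD,
              max_diameter: int = 3, allow_regional_fallback: bool = True,
              min_acf_pairs: int = 50) -> FillResult:
    """Estimate every missing land value of a daily LST cube.

    Per pixel: seasonal stats → normalized departures → 4σ outlier loop →
    power-law ACF → temporal Kriging of each missing time. Per day: the
    regional mean departure A_avg. Each missing value is then
    (1−E)·G + E·A_avg, rescaled by the pixel's MEAN/STD for that
    day-of-year; its variance is E·STD². Observed values (that survive the
    outlier loop) pass through unchanged.
    """
    nt, ny, nx = grid.shape
    doys = grid.doy()
    times = grid.dates.astype(int)
    times = times - times.min()
    land = grid.land_mask

    mean = np.full((N_DOY, ny, nx), np.nan)
    std = np.full((N_DOY, ny, nx), np.nan)
    source = np.full((ny, nx), SOURCE_FITTED, dtype=int)
    z_cube = np.full((nt, ny, nx), np.nan)
    patho = np.zeros((ny, nx), dtype=bool)
    acf_models = {}
    n_outliers = 0

    doy_grid = np.arange(1, N_DOY + 1)
    for y in range(ny):
        for x in range(nx):
            if not land[y, x]:
                continue
            v = grid.values[:, y, x]
            ok = grid.valid[:, y, x] & np.isfinite(v)
            if classify_pathological(grid.dates, ok):
                patho[y, x] = True
                continue
            try:
                model, doy_std = pixel_seasonal_stats(
                    grid.dates, v, ok, repeat_period=repeat_period,
                    spike_factor=spike_factor,
                )
            except DegeneratePixelError:
                patho[y, x] = True
                continue
            z = normalize_departures(grid.dates, v, model, doy_std, valid=ok)
            try:
                z, removed = outlier_loop(z, threshold=outlier_threshold)
            except ValueError:
                patho[y, x] = True
                continue
            n_outliers += removed
            z_cube[:, y, x] = z
            # per-DOY MEAN: average of the seasonal curve over record dates
            curve = model.evaluate(grid.dates)
            s = np.zeros(N_DOY)
            c = np.zeros(N_DOY)
            np.add.at(s, doys - 1, curve)
            np.add.at(c, doys - 1, 1)
            with np.errstate(invalid="ignore"):
                mean[:, y, x] = np.where(c > 0, s / np.maximum(c, 1), np.nan)
            # DOYs absent from the record: evaluate mid-record year curve
            absent = c == 0
            if absent.any():
                mid = times[len(times) // 2]
                mean[absent, y, x] = model.evaluate(
                    grid.dates[len(times) // 2].astype("datetime64[D]")
                    + (doy_grid[absent] - int(doys[len(times) // 2])).astype("timedelta64[D]")
                )
            std[:, y, x] = doy_std
            acf = fit_acf(z, times, min_pairs=min_acf_pairs)
            if acf is not None:
                acf_models[(y, x)] = acf

    clim = PixelClimatology(mean=mean, std=std, source=source)
    if patho.any():
        clim = complete_pathological(
            clim, patho, land, max_diameter=max_diameter,
            allow_regional_fallback=allow_regional_fallback,
        )

    # regional mean departure per calendar day (0 when nothing is valid)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        a_avg = np.nanmean(
            np.where(land[None, :, :], z_cube, np.nan).reshape(nt, -1), axis=1
        )
    a_avg = np.where(np.isfinite(a_avg), a_avg, 0.0)

    out_values = grid.values.copy()
    out_valid = grid.valid.copy()
    provenance = np.zeros((nt, ny, nx), dtype=np.uint8)
    variance = np.zeros((nt, ny, nx))

    for y in range(ny):
        for x in range(nx):
            if not land[y, x]:
                continue
            z = z_cube[:, y, x]
            observed = grid.valid[:, y, x] & np.isfinite(grid.values[:, y, x])
            kept = observed & np.isfinite(z)  # survived the outlier loop
            if patho[y, x]:
                kept = observed  # no departure series; keep raw observations
            missing = ~kept
            if not missing.any():
                continue
            acf = acf_models.get((y, x))
            mu = clim.mean[doys - 1, y, x]
            sg = clim.std[doys - 1, y, x]
            for t in np.nonzero(missing)[0]:
                if acf is not None:
                    G, E = temporal_krige(z, times, times[t], acf)
                else:
                    G, E = 0.0, 1.0
                out_values[t, y, x] = blend_and_restore(
                    G, E, a_avg[t], mu[t], sg[t]
                )
                variance[t, y, x] = E * sg[t] ** 2
                provenance[t, y, x] = PROV_FILLED
                out_valid[t, y, x] = True

    filled = GridTimeSeries(
        dates=grid.dates, values=out_values, valid=out_valid,
        land_mask=land, lats=grid.lats, lons=grid.lons,
    )
    return FillResult(grid=filled, provenance=provenance, variance=variance,
                      climatology=clim, n_outliers=n_outliers)


class LSTGapFiller:
    """Estimator-style wrapper around :func:`fill_grid`.

    ``transform`` fills a :class:`GridTimeSeries`; fitted attributes expose
    the per-pixel climatology and fill diagnostics.
    """

    def __init__(self, *, repeat_period: float = 16.0, spike_factor: float = 4.0,
                 outlier_threshold: float = OUTLIER_THRESHOLD, max_diameter: int = 3,
                 allow_regional_fallback: bool = True, min_acf_pairs: int = 50):
        self.repeat_period = repeat_period
        self.spike_factor = spike_factor
        self.outlier_threshold = outlier_threshold
        self.max_diameter = max_diameter
        self.allow_regional_fallback = allow_regional_fallback
        self.min_acf_pairs = min_acf_pairs

    def get_params(self, deep=True):
        return {
            "repeat_period": self.repeat_period,
            "spike_factor": self.spike_factor,
            "outlier_threshold": self.outlier_threshold,
            "max_diameter": self.max_diameter,
            "allow_regional_fallback": self.allow_regional_fallback,
            "min_acf_pairs": self.min_acf_pairs,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, grid: GridTimeSeries, y=None):
        self.result_ = fill_grid(grid, **self.get_params())
        self.climatology_ = self.result_.climatology
        return self

    def transform(self, grid: GridTimeSeries) -> GridTimeSeries:
        if not hasattr(self, "result_"):
            self.fit(grid)
        return self.result_.grid

    def fit_transform(self, grid: GridTimeSeries, y=None) -> GridTimeSeries:
        return self.fit(grid).transform(grid)
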