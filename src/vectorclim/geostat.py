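"""Day-of-year semivariograms and simple Kriging with prediction error.

The spatial model is a stationary, isotropic anomaly field with semivariogram

    γ(d) = nugget + (sill − nugget) · (1 − 2^(−d/λ)),

so that the correlation drops to one half exactly at d = λ — λ is the
half-correlation distance, γ(∞) the sill. Because daily temperature
variability changes through the year, sill and λ are fitted independently
for every day-of-year from pooled multi-year (distance, squared anomaly
difference) pairs, then smoothed along the DOY axis with a circular
median-then-mean 31-day window filter.

Simple Kriging (known mean 0 for anomalies) then gives a prediction and a
prediction standard error at every target; the error grows from 0 at a
station (nugget 0) to √sill far from all stations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from ._dates import N_DOY

EARTH_RADIUS_KM = 6371.0088  # WGS84 mean radius


class VariogramFitError(RuntimeError):
    """Variogram fit failed for a day-of-year (too few bins or no convergence)."""


class SingularCovarianceError(np.linalg.LinAlgError):
    """Kriging covariance matrix is singular; a nugget term usually fixes this."""


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_distances_km(lats, lons) -> np.ndarray:
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    return haversine_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])


def variogram_model(d, sill, lam, nugget=0.0):
    """γ(d) = nugget + (sill − nugget)(1 − 2^(−d/λ))."""
    return nugget + (sill - nugget) * (1.0 - np.exp2(-np.asarray(d, dtype=float) / lam))


def covariance_model(d, sill, lam, nugget=0.0):
    """Covariance consistent with the variogram: C(d) = (sill − nugget)·2^(−d/λ)."""
    return (sill - nugget) * np.exp2(-np.asarray(d, dtype=float) / lam)


def empirical_semivariance(stations, doy: int, *, half: bool = True):
    """Pooled (distance, semivariance) pairs for one day-of-year.

    For every unordered station pair and every year in which both stations
    have a valid anomaly on that DOY, emits the great-circle distance in km
    and ½·(aᵢ−aⱼ)² (the ½ is dropped when ``half=False``).

    Parameters
    ----------
    stations : sequence of (StationSeries-like, anomalies)
        Each element must expose ``.lat``, ``.lon``, ``.dates`` and an
        aligned anomaly array (NaN where invalid); accepts
        ``(series, anomalies)`` tuples or objects with ``.anomalies``.
    doy : int
        Day-of-year 1..365.

    Returns
    -------
    (distances, gammas) : two float arrays, possibly empty
    """
    import pandas as pd

    recs = []  # per station: dict year -> anomaly on this doy
    locs = []
    for item in stations:
        if isinstance(item, tuple):
            s, anom = item
        else:
            s, anom = item, item.anomalies
        anom = np.asarray(anom, dtype=float)
        doys = s.doy()
        years = pd.DatetimeIndex(s.dates.astype("datetime64[ns]")).year.to_numpy()
        sel = (doys == doy) & np.isfinite(anom)
        recs.append(dict(zip(years[sel], anom[sel])))
        locs.append((s.lat, s.lon))

    dists, gammas = [], []
    scale = 0.5 if half else 1.0
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            common = recs[i].keys() & recs[j].keys()
            if not common:
                continue
            d = haversine_km(locs[i][0], locs[i][1], locs[j][0], locs[j][1])
            for yr in common:
                dists.append(d)
                gammas.append(scale * (recs[i][yr] - recs[j][yr]) ** 2)
    return np.asarray(dists, dtype=float), np.asarray(gammas, dtype=float)


def bin_pairs(dists, gammas, *, bin_width: float = 25.0, min_pairs: int = 10,
              max_dist: float | None = None):
    """Average pair semivariances in distance bins; drop sparse bins.

    Bins are ``bin_width`` km wide up to ``max_dist`` (default 1.5× the
    largest pair distance); bins with fewer than ``min_pairs`` pairs are
    dropped. Returns (bin_center, bin_mean, bin_count).
    """
    dists = np.asarray(dists, dtype=float)
    gammas = np.asarray(gammas, dtype=float)
    if len(dists) == 0:
        return np.array([]), np.array([]), np.array([], dtype=int)
    if max_dist is None:
        max_dist = 1.5 * dists.max()
    edges = np.arange(0.0, max_dist + bin_width, bin_width)
    idx = np.digitize(dists, edges) - 1
    centers, means, counts = [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n >= min_pairs:
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(gammas[sel].mean())
            counts.append(n)
    return np.asarray(centers), np.asarray(means), np.asarray(counts, dtype=int)


def fit_variogram(dists, gammas, *, bin_width: float = 25.0, min_pairs: int = 10,
                  fit_nugget: bool = False):
    """Least-squares fit of the variogram model to binned pair semivariances.

    Returns
    -------
    (sill, lam, nugget) and a diagnostics dict (bin centers/means/counts,
    residual RMS). Raises VariogramFitError when fewer than 3 usable bins
    remain or the optimizer fails.
    """
    centers, means, counts = bin_pairs(
        dists, gammas, bin_width=bin_width, min_pairs=min_pairs
    )
    if len(centers) < 3:
        raise VariogramFitError(
            f"need >= 3 populated distance bins, got {len(centers)}"
        )
    sill0 = float(means.max())
    above = means >= 0.5 * sill0
    lam0 = float(centers[np.argmax(above)]) if above.any() else float(centers.mean())
    lam0 = max(lam0, 1.0)
    try:
        if fit_nugget:
            popt, _ = curve_fit(
                lambda d, s, l, n: variogram_model(d, s, l, n),
                centers, means, p0=[sill0, lam0, 0.0],
                bounds=([1e-12, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
            sill, lam, nugget = popt
        else:
            popt, _ = curve_fit(
                lambda d, s, l: variogram_model(d, s, l),
                centers, means, p0=[sill0, lam0],
                bounds=([1e-12, 1e-6], [np.inf, np.inf]),
                maxfev=10000,
            )
            sill, lam = popt
            nugget = 0.0
    except (RuntimeError, ValueError) as exc:
        raise VariogramFitError(f"variogram fit did not converge: {exc}") from exc
    resid = means - variogram_model(centers, sill, lam, nugget)
    diag = {
        "bin_centers": centers, "bin_means": means, "bin_counts": counts,
        "resid_rms": float(np.sqrt(np.mean(resid ** 2))),
    }
    return (float(sill), float(lam), float(nugget)), diag


def median_mean_smooth(x, window: int = 31) -> np.ndarray:
    """Two-pass circular smoother: sliding median, then sliding mean.

    Both passes use the same odd, equally weighted window, treated
    circularly (day 365 is adjacent to day 1). NaN entries (e.g. DOYs whose
    variogram fit failed) are ignored inside the window and filled by the
    smoothing.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    n = len(x)
    half = window // 2

    def _windows(arr):
        padded = np.concatenate([arr[-half:], arr, arr[:half]])
        return np.lib.stride_tricks.sliding_window_view(padded, window)

    with np.errstate(all="ignore"):
        med = np.nanmedian(_windows(x), axis=1)
        out = np.nanmean(_windows(med), axis=1)
    return out


@dataclass
class VariogramDOY:
    """Per-day-of-year variogram parameters (length-365 arrays)."""

    sill: np.ndarray
    half_dist: np.ndarray
    nugget: np.ndarray = None

    def __post_init__(self):
        self.sill = np.asarray(self.sill, dtype=float)
        self.half_dist = np.asarray(self.half_dist, dtype=float)
        if self.nugget is None:
            self.nugget = np.zeros(N_DOY)
        self.nugget = np.asarray(self.nugget, dtype=float)
        for name in ("sill", "half_dist", "nugget"):
            if len(getattr(self, name)) != N_DOY:
                raise ValueError(f"{name} must have length {N_DOY}")

    def params(self, doy: int):
        """(sill, half_dist, nugget) for one DOY (1-based)."""
        i = int(doy) - 1
        return float(self.sill[i]), float(self.half_dist[i]), float(self.nugget[i])


def fit_variogram_doy(stations, *, half: bool = True, bin_width: float = 25.0,
                      min_pairs: int = 10, window: int = 31) -> VariogramDOY:
    """Fit sill/λ for every DOY and smooth along the year.

    DOYs where the fit fails are left NaN and filled by the circular
    median-mean smoothing pass over neighbouring days.
    """
    sill = np.full(N_DOY, np.nan)
    lam = np.full(N_DOY, np.nan)
    for d in range(1, N_DOY + 1):
        dists, gammas = empirical_semivariance(stations, d, half=half)
        try:
            (s, l, _), _ = fit_variogram(
                dists, gammas, bin_width=bin_width, min_pairs=min_pairs
            )
            sill[d - 1], lam[d - 1] = s, l
        except VariogramFitError:
            continue
    if np.all(np.isnan(sill)):
        raise VariogramFitError("variogram fit failed for every day-of-year")
    return VariogramDOY(
        sill=median_mean_smooth(sill, window),
        half_dist=median_mean_smooth(lam, window),
    )


@dataclass
class KrigedField:
    """Predicted surface and Kriging standard error on a lat/lon grid."""

    lats: np.ndarray
    lons: np.ndarray
    prediction: np.ndarray  # (nlat, nlon)
    std_error: np.ndarray  # (nlat, nlon)
    climatology_only: bool = False


class SimpleKriging(RegressorMixin, BaseEstimator):
    """Simple Kriging of a zero-mean anomaly field on the sphere.

    Covariance between observations at distance d (km) is
    ``(sill − nugget)·2^(−d/λ)`` with ``sill`` on the diagonal; the known
    mean is 0. ``predict(X, return_std=True)`` returns the BLUP and the
    Kriging standard error √(sill − c₀ᵀC⁻¹c₀).

    Parameters
    ----------
    sill : float
        Marginal variance of the field, (units)².
    half_dist : float
        Half-correlation distance λ in km.
    nugget : float
        Short-range/measurement variance; 0 by default. A small nugget
        stabilizes the solve when stations nearly coincide.
    max_stations : int or None
        If set, each prediction uses only the nearest ``max_stations``
        observations.
    """

    def __init__(self, sill: float = 1.0, half_dist: float = 100.0,
                 nugget: float = 0.0, max_stations: int | None = None):
        self.sill = sill
        self.half_dist = half_dist
        self.nugget = nugget
        self.max_stations = max_stations

    def fit(self, X, y):
        """X: (n, 2) array of (lat, lon) in degrees; y: anomalies."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_stations, 2) lat/lon")
        if len(X) != len(y) or len(y) == 0:
            raise ValueError("need at least one observation")
        if np.any(~np.isfinite(y)):
            raise ValueError("observations must be finite")
        self.X_ = X
        self.y_ = y
        D = pairwise_distances_km(X[:, 0], X[:, 1])
        C = covariance_model(D, self.sill, self.half_dist, self.nugget)
        np.fill_diagonal(C, self.sill)
        try:
            self._cho = cho_factor(C, lower=True)
        except LinAlgError as exc:
            raise SingularCovarianceError(
                "covariance matrix is singular (duplicate station locations?); "
                "include a nugget term"
            ) from exc
        self._Cinv_y = cho_solve(self._cho, y)
        return self

    def predict(self, X, return_std: bool = False):
        """Predict at (lat, lon) targets; optionally with Kriging std error."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.max_stations is not None and self.max_stations < len(self.y_):
            return self._predict_local(X, return_std)
        d0 = haversine_km(
            X[:, 0][:, None], X[:, 1][:, None],
            self.X_[:, 0][None, :], self.X_[:, 1][None, :],
        )
        c0 = covariance_model(d0, self.sill, self.half_dist, self.nugget)
        pred = c0 @ self._Cinv_y
        if not return_std:
            return pred
        var = self.sill - np.einsum("ij,ji->i", c0, cho_solve(self._cho, c0.T))
        return pred, np.sqrt(np.clip(var, 0.0, None))

    def _predict_local(self, X, return_std):
        pred = np.empty(len(X))
        std = np.empty(len(X))
        for i, (lat, lon) in enumerate(X):
            d = haversine_km(lat, lon, self.X_[:, 0], self.X_[:, 1])
            near = np.argsort(d)[: self.max_stations]
            sub = SimpleKriging(self.sill, self.half_dist, self.nugget).fit(
                self.X_[near], self.y_[near]
            )
            out = sub.predict([[lat, lon]], return_std=return_std)
            if return_std:
                pred[i], std[i] = out[0][0], out[1][0]
            else:
                pred[i] = out[0]
        return (pred, std) if return_std else pred

    def predict_grid(self, lats, lons) -> KrigedField:
        """Krige onto the tensor grid lats × lons."""
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        LA, LO = np.meshgrid(lats, lons, indexing="ij")
        targets = np.column_stack([LA.ravel(), LO.ravel()])
        pred, std = self.predict(targets, return_std=True)
        return KrigedField(
            lats=lats, lons=lons,
            prediction=pred.reshape(LA.shape), std_error=std.reshape(LA.shape),
        )


def simple_krige(obs_latlon, anomalies, lats, lons, vg, *,
                 max_stations: int | None = None) -> KrigedField:
    """Functional wrapper: Krige observations onto a lat/lon grid.

    ``vg`` is a (sill, half_dist, nugget) triple.
    """
    sill, lam, nugget = vg
    model = SimpleKriging(sill=sill, half_dist=lam, nugget=nugget,
                          max_stations=max_stations)
    model.fit(np.asarray(obs_latlon, dtype=float), anomalies)
    return model.predict_grid(lats, lons)
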