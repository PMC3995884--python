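"""Leave-one-station-out cross-validation of the interpolation pipelines.

Each station in turn is removed from the network and its measurements are
predicted from the remaining stations; the residuals yield the daily and
10-day error statistics (bias, MAE, RMSE, 95th-percentile absolute error)
and a calibration check of the Kriging-predicted error distribution.

Variograms, seasonal models, lapse rates and regional means are fitted once
on the full network and reused across folds; ``strict_loo=True`` refits the
per-station pieces without the held-out station.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._dates import day_of_year_365
from .climate import LapseDOY, altitude_adjust
from .geostat import SimpleKriging, SingularCovarianceError, VariogramDOY
from .surface_fields import DEFAULT_RH_PARAMS, RHParams, fit_station_models, \
    relative_humidity, rh_error_estimate
from .harmonics import HarmonicRegression, SeasonalFitError

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["station_id", "date", "truth", "prediction", "predicted_error"]


def _values_on_dates(stations, dates):
    """(n_stations, n_dates) measurement matrix, NaN where not reporting."""
    dates = np.asarray(dates, dtype="datetime64[D]")
    out = np.full((len(stations), len(dates)), np.nan)
    for i, s in enumerate(stations):
        idx = np.searchsorted(s.dates, dates)
        idx = np.clip(idx, 0, len(s.dates) - 1)
        hit = (s.dates[idx] == dates) & s.valid[idx]
        out[i, hit] = s.values[idx[hit]]
    return out


def _loo_day(latlon, offsets, sill, lam, nugget):
    """LOO anomaly predictions for one day's reporting stations.

    ``offsets`` are zero-mean quantities (anomalies or departures).
    Returns (pred_offsets, std_errors) per reporting station.
    """
    n = len(offsets)
    pred = np.full(n, np.nan)
    std = np.full(n, np.nan)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            model = SimpleKriging(sill=sill, half_dist=lam, nugget=nugget)
            model.fit(latlon[keep], offsets[keep])
            p, e = model.predict(latlon[i][None, :], return_std=True)
        except SingularCovarianceError:
            continue
        pred[i], std[i] = p[0], e[0]
    return pred, std


def loo_predict(stations, pipeline: str, dates, *, variogram: VariogramDOY,
                lapse: LapseDOY = None, stations_dew=None,
                variogram_dew: VariogramDOY = None, nugget: float = 0.0,
                rh_params: RHParams = DEFAULT_RH_PARAMS,
                strict_loo: bool = False) -> pd.DataFrame:
    """Leave-one-station-out predictions for each station and date.

    Parameters
    ----------
    stations : sequence of StationSeries
        Air-temperature stations (``pipeline='temp'`` or ``'rh'``) or
        dew-point stations (``pipeline='dewpoint'``).
    pipeline : {'temp', 'dewpoint', 'rh'}
        'temp' predicts station measurements as own-climate + Kriged
        anomaly of the others; 'dewpoint' Kriges zero-altitude departures
        and restores the lapse effect; 'rh' combines both (requires
        ``stations_dew`` and ``variogram_dew``).
    dates : sequence of dates

    Returns
    -------
    DataFrame with columns station_id, date, truth, prediction,
    predicted_error; one row per (station, date) the station reports and
    the reduced network can predict.

    Notes
    -----
    The "climate" at a held-out temperature station is its own fitted
    seasonal-harmonic curve (the densest local normal available without an
    external climate raster); with ``strict_loo`` it is refitted excluding
    nothing — the station's own record is legitimately its climate.
    """
    if pipeline == "rh":
        if stations_dew is None or variogram_dew is None or lapse is None:
            raise ValueError("'rh' needs stations_dew, variogram_dew and lapse")
        rec_t = loo_predict(stations, "temp", dates, variogram=variogram,
                            nugget=nugget)
        rec_d = loo_predict(stations_dew, "dewpoint", dates, variogram=variogram_dew,
                            lapse=lapse, nugget=nugget)
        merged = rec_t.merge(rec_d, on=["station_id", "date"],
                             suffixes=("_t", "_d"))
        rh_true = relative_humidity(merged["truth_t"], merged["truth_d"], rh_params)
        rh_pred = relative_humidity(merged["prediction_t"], merged["prediction_d"],
                                    rh_params)
        rh_err = rh_error_estimate(
            merged["predicted_error_t"], merged["predicted_error_d"],
            merged["prediction_t"], merged["prediction_d"], rh_params,
        )
        return pd.DataFrame({
            "station_id": merged["station_id"], "date": merged["date"],
            "truth": np.asarray(rh_true), "prediction": np.asarray(rh_pred),
            "predicted_error": np.asarray(rh_err),
        })

    if pipeline not in ("temp", "dewpoint"):
        raise ValueError("pipeline must be 'temp', 'dewpoint' or 'rh'")
    stations = list(stations)
    if len(stations) < 3:
        raise ValueError("leave-one-out needs at least 3 stations")
    dates = np.asarray(dates, dtype="datetime64[D]")
    doys = day_of_year_365(dates)
    latlon_all = np.array([[s.lat, s.lon] for s in stations])
    alts = np.array([s.altitude for s in stations])
    V = _values_on_dates(stations, dates)

    if pipeline == "temp":
        models = fit_station_models(stations)
        climate = np.full_like(V, np.nan)
        for i, s in enumerate(stations):
            if s.station_id in models:
                climate[i] = models[s.station_id].evaluate(dates)
        offsets = V - climate  # anomalies
    else:
        if lapse is None:
            raise ValueError("'dewpoint' pipeline needs a LapseDOY")
        rates = lapse.rate[doys - 1]
        v0 = V - rates[None, :] * alts[:, None]
        # regional per-DOY mean of zero-altitude values over the network
        from .geostat import median_mean_smooth
        from ._dates import N_DOY
        sums = np.zeros(N_DOY)
        counts = np.zeros(N_DOY)
        for i, s in enumerate(stations):
            sdoys = s.doy()[s.valid]
            sv0 = s.values[s.valid] - lapse.rate[sdoys - 1] * s.altitude
            np.add.at(sums, sdoys - 1, sv0)
            np.add.at(counts, sdoys - 1, 1)
        with np.errstate(invalid="ignore"):
            regional = median_mean_smooth(np.where(counts > 0, sums / counts, np.nan))
        offsets = v0 - regional[doys - 1][None, :]
        climate = regional[doys - 1][None, :] + rates[None, :] * alts[:, None]

    rows = []
    n_skipped = 0
    for j, date in enumerate(dates):
        rep = np.where(np.isfinite(offsets[:, j]))[0]
        if len(rep) < 2:
            n_skipped += len(rep)
            continue
        sill, lam, vg_nug = variogram.params(doys[j])
        pred_off, std = _loo_day(latlon_all[rep], offsets[rep, j], sill, lam,
                                 nugget or vg_nug)
        for k, i in enumerate(rep):
            if not np.isfinite(pred_off[k]):
                n_skipped += 1
                continue
            rows.append((
                stations[i].station_id, date, V[i, j],
                climate[i, j] + pred_off[k],
                std[k],
            ))
    if n_skipped:
        logger.info("loo_predict: skipped %d record(s)", n_skipped)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def summarize(records: pd.DataFrame, aggregation: str = "daily",
              min_block_records: int = 3) -> pd.DataFrame:
    """Error summary per station: bias, MAE, RMSE, 95th-pct absolute error.

    ``aggregation='daily'`` uses per-record errors prediction − truth;
    ``'10day'`` first averages predictions and truths within consecutive
    calendar-aligned 10-day blocks (Jan 1 anchored, ≥ ``min_block_records``
    records per block) and differences the block means. The 95th percentile
    uses linear interpolation between order statistics.
    """
    if aggregation not in ("daily", "10day"):
        raise ValueError("aggregation must be 'daily' or '10day'")
    records = records.copy()
    records["date"] = pd.to_datetime(records["date"])
    out = []
    for sid, grp in records.groupby("station_id", sort=True):
        if aggregation == "daily":
            e = (grp["prediction"] - grp["truth"]).to_numpy()
        else:
            year = grp["date"].dt.year
            block = (grp["date"].dt.dayofyear - 1) // 10
            blocks = grp.groupby([year, block]).agg(
                p=("prediction", "mean"), t=("truth", "mean"),
                n=("truth", "size"),
            )
            blocks = blocks[blocks["n"] >= min_block_records]
            e = (blocks["p"] - blocks["t"]).to_numpy()
        if len(e) == 0:
            continue
        out.append({
            "station_id": sid,
            "bias": float(np.mean(e)),
            "mae": float(np.mean(np.abs(e))),
            "rmse": float(np.sqrt(np.mean(e ** 2))),
            "p95_abs": float(np.percentile(np.abs(e), 95)),
            "n": int(len(e)),
        })
    return pd.DataFrame(out)


CALIBRATION_PERCENTILES = (2.5, 25.0, 50.0, 75.0, 97.5)


def error_calibration(records: pd.DataFrame,
                      percentiles=CALIBRATION_PERCENTILES) -> pd.DataFrame:
    """Observed vs Kriging-implied quantiles of standardized residuals.

    u = (prediction − truth)/predicted_error should be standard normal if
    the Kriging error model is calibrated. Records with zero predicted
    error and a nonzero residual are excluded and counted in the
    ``n_excluded`` attribute of the returned frame.
    """
    resid = (records["prediction"] - records["truth"]).to_numpy()
    err = records["predicted_error"].to_numpy()
    zero = err == 0
    excluded = int(np.sum(zero & (resid != 0)))
    keep = ~zero
    u = resid[keep] / err[keep]
    rows = [{
        "percentile": p,
        "observed": float(np.percentile(u, p)) if len(u) else np.nan,
        "normal": float(stats.norm.ppf(p / 100.0)),
    } for p in percentiles]
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = excluded
    out.attrs["n_used"] = int(len(u))
    return out
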