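"""Daily air-temperature and relative-humidity surfaces.

Air temperature on a date is the daily climate normal plus the simple-Kriged
field of that day's station anomalies (measurement minus the station's own
seasonal-harmonic curve). Dew point has no dense normal: station values are
reduced to zero-altitude equivalents with the regional day-of-year lapse
rate, their departures from the regional DOY mean are Kriged, and the
altitude effect is restored with a digital elevation model. Relative
humidity then follows from the August-Roche-Magnus approximation

    RH = 100 · exp(a·Td/(b+Td) − a·T/(b+T)),   a = 17.271, b = 237.7 °C,

with first-order error propagation assuming the temperature and dew-point
interpolation errors are uncorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._dates import day_of_year_365
from .climate import DailyClimate, LapseDOY, altitude_adjust
from .geostat import (
    N_DOY,
    KrigedField,
    SimpleKriging,
    VariogramDOY,
    median_mean_smooth,
)
from .harmonics import HarmonicRegression, SeasonalFitError


@dataclass
class RHParams:
    """Magnus-formula constants (a dimensionless, b in °C)."""

    a: float = 17.271
    b: float = 237.7


DEFAULT_RH_PARAMS = RHParams()


def _gamma(x, p: RHParams):
    return p.a * x / (p.b + x)


def relative_humidity(T, Td, params: RHParams = DEFAULT_RH_PARAMS,
                      cap: bool = False):
    """Relative humidity (%) from air temperature and dew point (°C).

    Values above 100% occur when Td > T (an indication precipitation may
    have taken place); ``cap=True`` clips them to 100%.
    """
    T = np.asarray(T, dtype=float)
    Td = np.asarray(Td, dtype=float)
    p = params
    if np.any(T <= -p.b) or np.any(Td <= -p.b):
        raise ValueError(f"T and Td must exceed -b = {-p.b} °C")
    rh = 100.0 * np.exp(_gamma(Td, p) - _gamma(T, p))
    if cap:
        rh = np.minimum(rh, 100.0)
    return rh if rh.ndim else float(rh)


def rh_error_estimate(T_err, Td_err, T, Td, params: RHParams = DEFAULT_RH_PARAMS):
    """First-order RH error from independent T and Td errors (both in °C).

    Uses the analytic partials of the Magnus formula:
    ∂RH/∂Td = RH·a·b/(b+Td)² > 0 and ∂RH/∂T = −RH·a·b/(b+T)² < 0.
    """
    p = params
    rh = 100.0 * np.exp(_gamma(np.asarray(Td, float), p) - _gamma(np.asarray(T, float), p))
    dTd = rh * p.a * p.b / (p.b + np.asarray(Td, float)) ** 2
    dT = -rh * p.a * p.b / (p.b + np.asarray(T, float)) ** 2
    var = dT ** 2 * np.asarray(T_err, float) ** 2 + dTd ** 2 * np.asarray(Td_err, float) ** 2
    out = np.sqrt(var)
    return out if out.ndim else float(out)


def fit_station_models(stations):
    """Seasonal-harmonic model per station; stations that cannot be fitted
    (too sparse) are dropped. Returns {station_id: SeasonalModel}."""
    models = {}
    for s in stations:
        try:
            models[s.station_id] = (
                HarmonicRegression()
                .fit(s.dates[s.valid], s.values[s.valid])
                .model_
            )
        except SeasonalFitError:
            continue
    return models


def _reporting_on(stations, date):
    """Stations with a valid measurement on the given calendar date."""
    date = np.datetime64(date, "D")
    out = []
    for s in stations:
        idx = np.searchsorted(s.dates, date)
        if idx < len(s.dates) and s.dates[idx] == date and s.valid[idx]:
            out.append((s, float(s.values[idx])))
    return out


class AirTemperatureInterpolator(BaseEstimator):
    """Daily air-temperature surfaces from stations + a daily climate normal.

    Parameters
    ----------
    climate : DailyClimate
        Daily normal surfaces on the target grid.
    variogram : VariogramDOY
        Smoothed per-DOY sill and half-correlation distance.
    nugget : float
        Optional nugget variance for the Kriging solve.

    Attributes
    ----------
    models_ : dict
        Seasonal-harmonic model per qualifying station.
    """

    def __init__(self, climate: DailyClimate, variogram: VariogramDOY,
                 nugget: float = 0.0, max_stations: int | None = None):
        self.climate = climate
        self.variogram = variogram
        self.nugget = nugget
        self.max_stations = max_stations

    def fit(self, stations, y=None):
        self.stations_ = [s for s in stations]
        self.models_ = fit_station_models(self.stations_)
        return self

    def predict(self, date) -> KrigedField:
        doy = int(day_of_year_365([np.datetime64(date, "D")])[0])
        sill, lam, _ = self.variogram.params(doy)
        normal = self.climate.for_doy(doy)
        reporting = [
            (s, v) for s, v in _reporting_on(self.stations_, date)
            if s.station_id in self.models_
        ]
        if not reporting:
            return KrigedField(
                lats=self.climate.lats, lons=self.climate.lons,
                prediction=normal.copy(),
                std_error=np.full_like(normal, np.sqrt(sill)),
                climatology_only=True,
            )
        latlon = np.array([[s.lat, s.lon] for s, _ in reporting])
        anoms = np.array([
            v - float(self.models_[s.station_id].evaluate([np.datetime64(date, "D")])[0])
            for s, v in reporting
        ])
        krig = SimpleKriging(sill=sill, half_dist=lam, nugget=self.nugget,
                             max_stations=self.max_stations)
        krig.fit(latlon, anoms)
        fld = krig.predict_grid(self.climate.lats, self.climate.lons)
        fld.prediction = normal + fld.prediction
        return fld


class DewPointInterpolator(BaseEstimator):
    """Daily dew-point surfaces via zero-altitude Kriging + lapse restore.

    Station dew points are reduced to zero altitude with the day-of-year
    lapse rate, Kriged as departures from the regional DOY mean of
    zero-altitude values (simple Kriging needs a known mean), then the mean
    is added back and the altitude effect restored with the DEM.
    """

    def __init__(self, lapse: LapseDOY, variogram: VariogramDOY,
                 dem: np.ndarray = None, lats=None, lons=None,
                 nugget: float = 0.0, max_stations: int | None = None):
        self.lapse = lapse
        self.variogram = variogram
        self.dem = dem
        self.lats = lats
        self.lons = lons
        self.nugget = nugget
        self.max_stations = max_stations

    def fit(self, stations, y=None):
        self.stations_ = [s for s in stations]
        # regional DOY mean of zero-altitude equivalents, pooled over years
        sums = np.zeros(N_DOY)
        counts = np.zeros(N_DOY)
        for s in self.stations_:
            doys = s.doy()[s.valid]
            v0 = altitude_adjust(
                s.values[s.valid], s.altitude,
                self.lapse.rate[doys - 1], "remove",
            )
            np.add.at(sums, doys - 1, v0)
            np.add.at(counts, doys - 1, 1)
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, sums / counts, np.nan)
        self.regional_mean_ = median_mean_smooth(mean)
        return self

    def predict(self, date) -> KrigedField:
        doy = int(day_of_year_365([np.datetime64(date, "D")])[0])
        sill, lam, _ = self.variogram.params(doy)
        rate = self.lapse.for_doy(doy)
        mean0 = float(self.regional_mean_[doy - 1])
        dem = np.zeros((len(self.lats), len(self.lons))) if self.dem is None \
            else np.asarray(self.dem, dtype=float)
        reporting = _reporting_on(self.stations_, date)
        if not reporting:
            pred0 = np.full(dem.shape, mean0)
            return KrigedField(
                lats=np.asarray(self.lats), lons=np.asarray(self.lons),
                prediction=altitude_adjust(pred0, dem, rate, "restore"),
                std_error=np.full(dem.shape, np.sqrt(sill)),
                climatology_only=True,
            )
        latlon = np.array([[s.lat, s.lon] for s, _ in reporting])
        departures = np.array([
            altitude_adjust(v, s.altitude, rate, "remove") - mean0
            for s, v in reporting
        ])
        krig = SimpleKriging(sill=sill, half_dist=lam, nugget=self.nugget,
                             max_stations=self.max_stations)
        krig.fit(latlon, departures)
        fld = krig.predict_grid(self.lats, self.lons)
        td0 = fld.prediction + mean0
        fld.prediction = altitude_adjust(td0, dem, rate, "restore")
        return fld


def air_temperature_day(stations, climate: DailyClimate, vg: VariogramDOY,
                        date, **kw) -> KrigedField:
    """One day's air-temperature surface (climate normal + Kriged anomaly)."""
    return AirTemperatureInterpolator(climate, vg, **kw).fit(stations).predict(date)


def dew_point_day(stations, lapse: LapseDOY, vg_dew: VariogramDOY,
                  dem, lats, lons, date, **kw) -> KrigedField:
    """One day's dew-point surface (zero-altitude Kriging + lapse restore)."""
    interp = DewPointInterpolator(lapse, vg_dew, dem=dem, lats=lats, lons=lons, **kw)
    return interp.fit(stations).predict(date)


def relative_humidity_day(t_field: KrigedField, td_field: KrigedField,
                          params: RHParams = DEFAULT_RH_PARAMS,
                          cap: bool = False) -> KrigedField:
    """Combine T and Td surfaces into an RH surface with propagated error."""
    rh = relative_humidity(t_field.prediction, td_field.prediction, params, cap)
    err = rh_error_estimate(
        t_field.std_error, td_field.std_error,
        t_field.prediction, td_field.prediction, params,
    )
    return KrigedField(
        lats=t_field.lats, lons=t_field.lons,
        prediction=np.asarray(rh), std_error=np.asarray(err),
        climatology_only=t_field.climatology_only or td_field.climatology_only,
    )
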