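"""Daily weather-station series: ingestion, validation and quality filtering.

A station qualifies for interpolation only if its record is dense enough to
support seasonal (Fourier) extraction: at least 61 valid measurements inside
some 365-day window of its lifetime, and no more than 30 consecutive
day-of-year bins (wrapping at year end) without any measurement across all
years pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dates import N_DOY, day_of_year_365

logger = logging.getLogger(__name__)

#: Default sentinel values marking a missing measurement (GSOD conventions).
DEFAULT_SENTINELS = (9999.9, 999.9)

#: Quality thresholds: minimum valid measurements in one 365-day window,
#: and maximum tolerated circular DOY gap.
MIN_WINDOW_COUNT = 61
MAX_DOY_GAP = 30

REQUIRED_COLUMNS = ("station_id", "lat", "lon", "altitude_m", "date", "value")


class StationFormatError(ValueError):
    """Raised for malformed station tables (missing columns, duplicates)."""


@dataclass
class StationSeries:
    """One station's daily measurement series with a validity mask.

    Parameters
    ----------
    station_id : str
    lat, lon : float
        Location in decimal degrees (WGS84).
    altitude : float
        Station altitude in meters.
    dates : ndarray of datetime64[D]
        Strictly increasing calendar dates.
    values : ndarray of float
        Measurement per date, °C (air temperature or dew point).
    valid : ndarray of bool
        Mask aligned with ``dates``; values are finite wherever True.
    """

    station_id: str
    lat: float
    lon: float
    altitude: float
    dates: np.ndarray
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.dates) == len(self.values) == len(self.valid)):
            raise ValueError("dates, values and valid must have equal length")
        if len(self.dates) > 1 and not np.all(np.diff(self.dates).astype(int) > 0):
            raise ValueError(f"station {self.station_id}: dates not strictly increasing")
        if not (-90.0 <= self.lat <= 90.0) or not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"station {self.station_id}: lat/lon out of range")
        if np.any(~np.isfinite(self.values[self.valid])):
            raise ValueError(f"station {self.station_id}: non-finite value marked valid")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def doy(self) -> np.ndarray:
        """Day-of-year index (1..365, Feb 29 -> 59) for each date."""
        return day_of_year_365(self.dates)


@dataclass
class QualityReport:
    """Diagnosis record produced by :func:`passes_quality`."""

    passed: bool
    window_count: int
    max_gap: int
    failed_rules: tuple = field(default_factory=tuple)


def read_station_table(path, *, sentinels=DEFAULT_SENTINELS, fahrenheit: bool = False):
    """Read one or more station CSV tables into :class:`StationSeries`.

    Expected header: ``station_id,lat,lon,altitude_m,date,value`` with
    ISO-8601 dates. Rows whose value is unparseable or equals a sentinel are
    kept but marked invalid; the rejected-row count is logged.

    Parameters
    ----------
    path : str, Path or sequence thereof
        CSV file(s); multiple files for the same station are merged.
    sentinels : sequence of float
        Values treated as missing (default GSOD conventions).
    fahrenheit : bool
        If True, convert valid values from °F to °C.

    Returns
    -------
    dict mapping station id to StationSeries
    """
    paths = [path] if isinstance(path, (str, bytes)) or hasattr(path, "open") else list(path)
    frames = []
    for p in paths:
        df = pd.read_csv(p, dtype={"station_id": str})
        missing = set(REQUIRED_COLUMNS) - set(df.columns)
        if missing:
            raise StationFormatError(f"{p}: missing required column(s) {sorted(missing)}")
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)

    dup = df.duplicated(subset=["station_id", "date"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise StationFormatError(
            f"duplicate (station, date): station {first['station_id']} on {first['date']}"
        )

    values = pd.to_numeric(df["value"], errors="coerce")
    valid = values.notna()
    for s in sentinels:
        valid &= values != s
    n_rejected = int((~valid).sum())
    if n_rejected:
        logger.info("read_station_table: %d row(s) marked invalid", n_rejected)
    df = df.assign(_value=values.fillna(np.nan), _valid=valid)

    out = {}
    for sid, grp in df.groupby("station_id", sort=True):
        grp = grp.sort_values("date")
        vals = grp["_value"].to_numpy(dtype=float)
        mask = grp["_valid"].to_numpy(dtype=bool)
        if fahrenheit:
            vals = np.where(mask, (vals - 32.0) * 5.0 / 9.0, vals)
        vals = np.where(mask, vals, np.nan)
        out[sid] = StationSeries(
            station_id=sid,
            lat=float(grp["lat"].iloc[0]),
            lon=float(grp["lon"].iloc[0]),
            altitude=float(grp["altitude_m"].iloc[0]),
            dates=grp["date"].to_numpy(dtype="datetime64[D]"),
            values=vals,
            valid=mask,
        )
    return out


def doy_histogram(s: StationSeries) -> np.ndarray:
    """Histogram of valid-measurement counts by day-of-year.

    Returns a length-365 integer array; ``counts[d-1]`` is the number of
    valid measurements falling on DOY ``d`` across all years.
    """
    counts = np.zeros(N_DOY, dtype=int)
    if len(s) == 0:
        return counts
    doys = s.doy()[s.valid]
    np.add.at(counts, doys - 1, 1)
    return counts


def max_circular_gap(counts: np.ndarray) -> int:
    """Longest run of consecutive zero-count DOY bins, wrapping at year end."""
    counts = np.asarray(counts)
    if counts.sum() == 0:
        return N_DOY
    zero = counts == 0
    # duplicate the ring so wrap-around runs appear as one contiguous run
    z2 = np.concatenate([zero, zero])
    best = run = 0
    for flag in z2:
        run = run + 1 if flag else 0
        best = max(best, run)
    return min(best, N_DOY)


def _max_window_count(s: StationSeries, window_days: int = 365) -> int:
    """Max number of valid measurements in any sliding window of given length."""
    vdates = s.dates[s.valid]
    if len(vdates) == 0:
        return 0
    days = vdates.astype("datetime64[D]").astype(int)
    best = 0
    j = 0
    # two-pointer scan: window [days[i], days[i]+window_days-1]
    for i in range(len(days)):
        if j < i:
            j = i
        while j < len(days) and days[j] - days[i] < window_days:
            j += 1
        best = max(best, j - i)
    return best


def passes_quality(
    s: StationSeries,
    *,
    min_window_count: int = MIN_WINDOW_COUNT,
    max_doy_gap: int = MAX_DOY_GAP,
) -> QualityReport:
    """Apply the two reporting-density rules to a station.

    Passes iff (a) some 365-day window contains at least ``min_window_count``
    valid measurements, and (b) the circular DOY histogram has no zero-run
    longer than ``max_doy_gap`` days. Comparisons are inclusive: exactly 61
    measurements pass, a gap of exactly 30 passes.
    """
    window_count = _max_window_count(s)
    gap = max_circular_gap(doy_histogram(s))
    failed = []
    if window_count < min_window_count:
        failed.append("window_count")
    if gap > max_doy_gap:
        failed.append("doy_gap")
    return QualityReport(
        passed=not failed,
        window_count=window_count,
        max_gap=gap,
        failed_rules=tuple(failed),
    )
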