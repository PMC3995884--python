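"""Day-of-year indexing on a fixed 365-bin calendar.

All DOY-indexed arrays in this package are length 365 (index 1..365).
February 29 shares bin 59 with February 28 so that multi-decade series can
be pooled without a floating 366th bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25
N_DOY = 365


def day_of_year_365(dates) -> np.ndarray:
    """Map calendar dates to a 1..365 day-of-year index (Feb 29 -> 59).

    In leap years every date from Feb 29 onward is shifted down by one so
    that e.g. March 2 is DOY 61 in every year.
    """
    idx = pd.DatetimeIndex(np.asarray(dates, dtype="datetime64[ns]"))
    doy = idx.dayofyear.to_numpy()
    leap = idx.is_leap_year
    return doy - (leap & (doy >= 60)).astype(int)


def days_since_epoch(dates) -> np.ndarray:
    """Continuous time axis in days (float) since 1970-01-01."""
    d = np.asarray(dates, dtype="datetime64[ns]")
    return (d - np.datetime64("1970-01-01")) / np.timedelta64(1, "D")


def circular_doy_distance(d1, d2) -> np.ndarray:
    """Shortest circular distance between two DOY indices on a 365-day ring."""
    diff = np.abs(np.asarray(d1) - np.asarray(d2))
    return np.minimum(diff, N_DOY - diff)
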