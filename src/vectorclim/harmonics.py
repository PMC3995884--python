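"""Seasonal (Fourier) decomposition of incomplete daily series.

A daily series is modelled as a constant plus once-, twice- and
thrice-yearly sinusoids (period 365.25 days). Because station and satellite
records are full of holes, amplitudes are obtained by least-squares
projection of the *valid* samples onto the 7-function basis — equivalent to
orthogonalizing the harmonics over the valid time points — so that missing
data do not bias the amplitudes. A companion routine strips narrowband
instrument noise (e.g. the 16-day satellite repeat cycle) from the spectrum
while leaving the seasonal lines untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lombscargle
from sklearn.base import BaseEstimator, RegressorMixin

from ._dates import DAYS_PER_YEAR, days_since_epoch

N_HARMONICS = 3


class SeasonalFitError(ValueError):
    """Too few valid samples, or samples spanning less than half a period."""


class DegenerateDesignError(SeasonalFitError):
    """Valid sample times make the harmonic design matrix rank-deficient."""


def _as_days(t) -> np.ndarray:
    t = np.asarray(t)
    if np.issubdtype(t.dtype, np.datetime64):
        return days_since_epoch(t)
    return t.astype(float)


def harmonic_design(t_days: np.ndarray, period: float = DAYS_PER_YEAR) -> np.ndarray:
    """Design matrix [1, cos(kωt), sin(kωt)] for k = 1..3, ω = 2π/period."""
    t_days = np.asarray(t_days, dtype=float)
    cols = [np.ones_like(t_days)]
    for k in range(1, N_HARMONICS + 1):
        w = 2.0 * np.pi * k / period
        cols.append(np.cos(w * t_days))
        cols.append(np.sin(w * t_days))
    return np.column_stack(cols)


@dataclass
class SeasonalModel:
    """Constant + 1,2,3 cycles/year harmonic model of a daily series."""

    mean: float
    cos_amp: np.ndarray  # shape (3,), k = 1, 2, 3 cycles/year
    sin_amp: np.ndarray
    period: float = DAYS_PER_YEAR

    def __post_init__(self) -> None:
        self.cos_amp = np.asarray(self.cos_amp, dtype=float)
        self.sin_amp = np.asarray(self.sin_amp, dtype=float)

    @property
    def coef(self) -> np.ndarray:
        out = np.empty(1 + 2 * N_HARMONICS)
        out[0] = self.mean
        out[1::2] = self.cos_amp
        out[2::2] = self.sin_amp
        return out

    def evaluate(self, dates) -> np.ndarray:
        """Model value at the given dates (datetime64 or float days)."""
        t = _as_days(dates)
        return harmonic_design(np.atleast_1d(t), self.period) @ self.coef

    def amplitude(self, k: int) -> float:
        """Total amplitude sqrt(cos² + sin²) of the k-cycles/year component."""
        return float(np.hypot(self.cos_amp[k - 1], self.sin_amp[k - 1]))


class HarmonicRegression(RegressorMixin, BaseEstimator):
    """Least-squares seasonal-harmonic regression tolerant of missing data.

    Parameters
    ----------
    period : float
        Fundamental period in days (365.25 by default).
    min_samples : int
        Minimum number of valid samples required to fit.

    Attributes
    ----------
    model_ : SeasonalModel
        Fitted mean and harmonic amplitudes.
    n_valid_ : int
        Number of samples the fit used.
    """

    def __init__(self, period: float = DAYS_PER_YEAR, min_samples: int = 7):
        self.period = period
        self.min_samples = min_samples

    def fit(self, X, y):
        t = _as_days(np.asarray(X).ravel())
        y = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(y)
        t, y = t[ok], y[ok]
        if len(t) < max(self.min_samples, 1 + 2 * N_HARMONICS):
            raise SeasonalFitError(
                f"need >= {self.min_samples} valid samples, got {len(t)}"
            )
        if np.ptp(t) <= self.period / 2.0:
            raise SeasonalFitError(
                "valid samples must span more than half a period "
                f"({self.period / 2:.1f} days), got {np.ptp(t):.1f}"
            )
        B = harmonic_design(t, self.period)
        coef, _, rank, _ = np.linalg.lstsq(B, y, rcond=None)
        if rank < B.shape[1]:
            raise DegenerateDesignError(
                "harmonic design matrix is rank-deficient on the valid sample times"
            )
        self.model_ = SeasonalModel(
            mean=float(coef[0]), cos_amp=coef[1::2], sin_amp=coef[2::2],
            period=self.period,
        )
        self.n_valid_ = len(t)
        return self

    def predict(self, X):
        return self.model_.evaluate(np.asarray(X).ravel())


def fit_seasonal(dates, values, valid=None, period: float = DAYS_PER_YEAR) -> SeasonalModel:
    """Fit the 7-parameter seasonal model to the valid samples of a series."""
    values = np.asarray(values, dtype=float)
    if valid is not None:
        values = np.where(np.asarray(valid, dtype=bool), values, np.nan)
    return HarmonicRegression(period=period).fit(dates, values).model_


def subtract_seasonal(dates, values, model: SeasonalModel, valid=None) -> np.ndarray:
    """Anomalies value − model; invalid samples stay NaN."""
    values = np.asarray(values, dtype=float)
    anom = values - model.evaluate(dates)
    if valid is not None:
        anom = np.where(np.asarray(valid, dtype=bool), anom, np.nan)
    return anom


def _amplitude_spectrum(t, y, freqs):
    """Sinusoid amplitude at each frequency from the Lomb-Scargle periodogram."""
    omega = 2.0 * np.pi * np.asarray(freqs)
    power = lombscargle(t, y - y.mean(), omega)
    return np.sqrt(4.0 * power / len(y))


def remove_noise_harmonics(
    dates,
    values,
    valid=None,
    repeat_period: float = 16.0,
    spike_factor: float = 4.0,
    detection_factor: float = 4.0,
    period: float = DAYS_PER_YEAR,
) -> np.ndarray:
    """Strip the satellite repeat-cycle line and other narrowband spikes.

    Harmonics of the repeat cycle (frequencies m/repeat_period up to
    Nyquist) are removed when they stand above the local aperiodic signal
    level (amplitude > ``detection_factor`` × the local median amplitude);
    any other frequency whose amplitude exceeds ``spike_factor`` × the local
    median (±10 frequency bins, seasonal lines excluded) is removed as well.
    The conditional test keeps a pure-noise series essentially unchanged.
    The seasonal (0–3 cycles/year) components are protected: noise sinusoids
    are fitted *jointly* with the seasonal basis and only the noise part is
    subtracted.

    Missing samples are never interpolated; all fits use valid samples only.
    Returns the denoised values with NaN at invalid samples.
    """
    t_all = _as_days(np.asarray(dates).ravel())
    values = np.asarray(values, dtype=float).ravel()
    if valid is None:
        valid = np.isfinite(values)
    valid = np.asarray(valid, dtype=bool) & np.isfinite(values)

    out = np.where(valid, values, np.nan)
    t, y = t_all[valid], values[valid]
    if len(t) == 0 or np.allclose(y, y[0] if len(y) else 0.0):
        return out
    span = np.ptp(t)
    if span < 2 * repeat_period:
        raise SeasonalFitError("series must span at least two repeat periods")

    # frequency grid at the natural resolution of the record
    n_bins = int(span) // 2
    freqs = np.arange(1, n_bins + 1) / span  # cycles/day, up to ~Nyquist
    seasonal_f = np.arange(0, N_HARMONICS + 1) / period
    half_bin = 0.5 / span
    is_seasonal = np.zeros(n_bins, dtype=bool)
    for f in seasonal_f:
        is_seasonal |= np.abs(freqs - f) <= half_bin

    # candidate repeat-cycle harmonics (m/repeat_period up to Nyquist)
    repeat_f = np.arange(1, int(repeat_period // 2) + 1) / repeat_period
    repeat_f = repeat_f[repeat_f <= 0.5 + 1e-12]
    near_repeat = np.zeros(n_bins, dtype=bool)
    for f in repeat_f:
        near_repeat |= np.abs(freqs - f) <= half_bin

    amp = _amplitude_spectrum(t, y, freqs)
    background = np.where(is_seasonal | near_repeat, np.nan, amp)

    def _local_median(i):
        local = background[max(0, i - 10):min(n_bins, i + 11)]
        local = local[np.isfinite(local)]
        return np.median(local) if len(local) >= 3 else np.inf

    # repeat-cycle lines: removed when they stand above the local level
    repeat_amp = _amplitude_spectrum(t, y, repeat_f)
    keep_repeat = []
    for f, a in zip(repeat_f, repeat_amp):
        i = int(np.argmin(np.abs(freqs - f)))
        if a > detection_factor * _local_median(i):
            keep_repeat.append(f)

    # other narrowband spikes against the local aperiodic level
    spikes = np.zeros(n_bins, dtype=bool)
    for i in range(n_bins):
        if is_seasonal[i] or near_repeat[i]:
            continue
        if amp[i] > spike_factor * _local_median(i):
            spikes[i] = True

    noise_f = np.concatenate([np.asarray(keep_repeat), freqs[spikes]])
    if len(noise_f) == 0:
        return out

    # joint fit: seasonal basis + noise sinusoids; subtract the noise part only
    B_seas = harmonic_design(t, period)
    noise_cols = []
    for f in noise_f:
        w = 2.0 * np.pi * f
        noise_cols.append(np.cos(w * t))
        noise_cols.append(np.sin(w * t))
    B = np.column_stack([B_seas] + noise_cols)
    coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
    noise_part = B[:, B_seas.shape[1]:] @ coef[B_seas.shape[1]:]
    out[valid] = y - noise_part
    return out
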