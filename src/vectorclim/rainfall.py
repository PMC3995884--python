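"""Rainfall-grid preprocessing and dry-spell / climatology diagnostics.

Coarse daily satellite rainfall estimates (RFE-style, 0.1° cells) are
cleaned — missing cells become 0 mm/day and values above 300 mm/day are
capped, both flagged — and bilinearly interpolated from cell centres onto
the finer analysis grid. Diagnostics follow the comparisons used for such
products: per-pixel longest dry spell over the record, and monthly mean
daily rainfall climatologies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

RAIN_CAP_MM = 300.0

#: provenance flag codes
FLAG_OBSERVED = 0
FLAG_CAPPED = 1
FLAG_MISSING_ZEROED = 2


class ExtentError(ValueError):
    """Target grid lies (partly) outside the raw grid's cell centres."""


@dataclass
class RainGrid:
    """Daily rainfall cube (mm/day ≥ 0) with provenance flags."""

    dates: np.ndarray  # datetime64[D]
    lats: np.ndarray
    lons: np.ndarray
    rain: np.ndarray  # (nt, nlat, nlon), in [0, cap]
    flags: np.ndarray = None  # (nt, nlat, nlon) uint8

    def __post_init__(self):
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.rain = np.asarray(self.rain, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(self.rain.shape, dtype=np.uint8)
        if np.any(self.rain < 0):
            raise ValueError("rainfall must be non-negative")


def preprocess(raw, raw_lats, raw_lons, dates, target_lats, target_lons,
               *, cap: float = RAIN_CAP_MM) -> RainGrid:
    """Clean a coarse rainfall cube and regrid it bilinearly.

    Missing cells (NaN) are set to 0 mm/day and values above ``cap`` are
    replaced by ``cap`` — both *before* interpolation, so bilinear weights
    never propagate missingness and the output stays within [0, cap].
    Provenance flags are transferred to the target grid by nearest
    neighbour.

    The target grid must be nested within the raw cell centres.
    """
    raw = np.asarray(raw, dtype=float)
    raw_lats = np.asarray(raw_lats, dtype=float)
    raw_lons = np.asarray(raw_lons, dtype=float)
    target_lats = np.asarray(target_lats, dtype=float)
    target_lons = np.asarray(target_lons, dtype=float)

    if (target_lats.min() < raw_lats.min() or target_lats.max() > raw_lats.max()
            or target_lons.min() < raw_lons.min() or target_lons.max() > raw_lons.max()):
        raise ExtentError("target grid extends beyond the raw grid's cell centres")

    missing = ~np.isfinite(raw)
    capped = np.isfinite(raw) & (raw > cap)
    clean = np.where(missing, 0.0, np.minimum(raw, cap))
    flags = np.zeros(raw.shape, dtype=np.uint8)
    flags[capped] = FLAG_CAPPED
    flags[missing] = FLAG_MISSING_ZEROED

    LA, LO = np.meshgrid(target_lats, target_lons, indexing="ij")
    pts = np.column_stack([LA.ravel(), LO.ravel()])
    nt = raw.shape[0]
    out = np.empty((nt, len(target_lats), len(target_lons)))
    out_flags = np.empty((nt, len(target_lats), len(target_lons)), dtype=np.uint8)
    # nearest-neighbour index maps for flags
    iy = np.abs(target_lats[:, None] - raw_lats[None, :]).argmin(axis=1)
    ix = np.abs(target_lons[:, None] - raw_lons[None, :]).argmin(axis=1)
    for t in range(nt):
        interp = RegularGridInterpolator(
            (raw_lats, raw_lons), clean[t], method="linear", bounds_error=True
        )
        out[t] = interp(pts).reshape(LA.shape)
        out_flags[t] = flags[t][np.ix_(iy, ix)]
    out = np.clip(out, 0.0, cap)
    return RainGrid(dates=dates, lats=target_lats, lons=target_lons,
                    rain=out, flags=out_flags)


def longest_dry_spell(rain, wet_threshold: float = 0.0) -> np.ndarray:
    """Per-pixel length (days) of the longest run with rain ≤ threshold.

    Accepts a RainGrid or a (nt, ...) array; returns an integer surface.
    """
    r = rain.rain if isinstance(rain, RainGrid) else np.asarray(rain, dtype=float)
    dry = r <= wet_threshold
    run = np.zeros(r.shape[1:], dtype=int)
    best = np.zeros(r.shape[1:], dtype=int)
    for t in range(r.shape[0]):
        run = np.where(dry[t], run + 1, 0)
        best = np.maximum(best, run)
    return best


def monthly_climatology(rain: RainGrid) -> np.ndarray:
    """Mean daily rainfall per calendar month: (12, nlat, nlon) mm/day."""
    months = pd.DatetimeIndex(rain.dates.astype("datetime64[ns]")).month.to_numpy()
    out = np.full((12,) + rain.rain.shape[1:], np.nan)
    for m in range(1, 13):
        sel = months == m
        if sel.any():
            out[m - 1] = rain.rain[sel].mean(axis=0)
    return out
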