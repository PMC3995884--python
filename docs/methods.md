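# Methods

This note documents the models, parameter choices and numerical decisions
behind `vectorclim`, and what the synthetic-data tests do and do not show
about real data.

## Station quality filter

A station (or satellite pixel) supports seasonal extraction only if its
record is dense enough. Two rules, both inclusive at the boundary:

1. **Window count** — at least 61 valid measurements inside some 365-day
   window of the record. The window slides over calendar days; the maximum
   is found with a two-pointer scan over the sorted valid dates (the
   maximizing window can always be anchored at a measurement).
2. **Day-of-year gap** — pooling all years into a 365-bin day-of-year
   histogram, no run of more than 30 consecutive empty bins, treating the
   index as circular (day 365 is adjacent to day 1).

February 29 shares bin 59 with February 28, keeping every DOY-indexed array
at length 365 across leap years.

## Seasonal harmonics with missing data

Daily series are modelled as constant + 1, 2, 3 cycles/year sinusoids with
period 365.25 days (avoids phase drift over multi-decade records). With
missing data the sinusoids are not orthogonal over the observed times, so
amplitudes are obtained by least-squares projection of the valid samples
onto the 7-function basis — the same projection an explicit Gram–Schmidt
orthogonalization over valid time points produces; we use a stable SVD
solve since the projection is unique. Preconditions: at least 7 valid
samples spanning more than half a period, and full design rank.

Under missing-completely-at-random deletion this estimator is unbiased; the
test suite verifies mean amplitude error below 2% of the true amplitude
over 200 replicates at 30% missingness.

### Repeat-cycle noise removal

Satellite series carry narrowband artifacts at the orbital repeat cycle
(16 days) and occasional spectral spikes. Candidate noise lines are the
repeat-cycle harmonics m/16 day⁻¹ up to Nyquist plus any frequency whose
Lomb–Scargle amplitude exceeds `spike_factor` (default 4) × the local
median amplitude in a ±10-bin window (seasonal lines excluded from the
background). Repeat-cycle lines are removed only when they stand above the
local aperiodic level (`detection_factor`, default 4× the local median):
removing a fixed set of lines from a pure-noise series would strip
O(√(k/n)) of its energy for no benefit, whereas a real repeat-cycle
artifact sits orders of magnitude above background. Detected lines are
fitted jointly with the seasonal basis on the valid samples and only the
noise part is subtracted, so the 0–3 cycles/year components are preserved
to numerical precision. Missing values are never interpolated before
spectral analysis.

## Day-of-year variogram and simple Kriging

The anomaly field is modelled as stationary and isotropic with

γ(d) = nugget + (sill − nugget)(1 − 2^(−d/λ)),
C(d) = (sill − nugget)·2^(−d/λ),

base-2 so that correlation halves exactly at d = λ ("half-correlation
distance"). A base-e variant differs only by rescaling λ by ln 2.

Per day-of-year, all station pairs and all years are pooled into
(great-circle distance, ½·Δanomaly²) pairs — the classical ½ factor is a
config switch (`semivariance_half`, default on). Pairs are averaged in
25 km bins up to 1.5× the largest separation; bins with fewer than 10
pairs are dropped; sill and λ are fitted by bounded least squares
(`scipy.optimize.curve_fit`). Days whose fit fails are left undefined and
filled by the smoothing pass: a circular 31-day sliding median followed by
a circular 31-day sliding mean, equal weights, NaN-aware.

Simple Kriging assumes the anomaly mean is known (zero). With observations
C and target covariances c₀: weights w = C⁻¹c₀, prediction wᵀa, variance
sill − c₀ᵀC⁻¹c₀ (floored at 0). The diagonal of C is the full sill; with
nugget 0 the predictor interpolates exactly and its error vanishes at
stations, rising to √sill far away. Duplicate station locations with
nugget 0 make C singular; the error message advises a nugget. Distances
are haversine on the WGS84 mean radius (6371.0088 km). All reporting
stations are used by default (`max_stations` available for large regions).

## Climate layers and lapse rates

Monthly climate normals are interpolated to daily by fitting the
7-parameter harmonic basis to the 12 monthly values anchored at mid-month
days-of-year (15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349) and
evaluating daily — an overdetermined least-squares fit, exact for any
signal in the harmonic span. Pixels with any missing month are masked.

Dew point lacks a dense climate normal, so a region-wide day-of-year lapse
rate (°C/m) is regressed (OLS) from raw (altitude, dew point) pairs pooled
over all years for that DOY, then median-mean smoothed along the year.
Regressing raw values rather than anomalies changes only the intercept,
which cancels in the remove/restore round trip. Fewer than 3 distinct
altitudes is an error; an altitude range under 100 m warns.

## Air-temperature and humidity surfaces

Air temperature on a date = daily climate normal + simple-Kriged station
anomalies for that date (per-station anomalies against each station's own
fitted seasonal curve). If no station reports, the surface falls back to
the climate normal with error √sill and is flagged `climatology_only`.

Dew point: station values → zero-altitude equivalents (subtract
rate·altitude) → departures from the regional day-of-year mean of
zero-altitude values (simple Kriging needs a known mean; the regional mean
is the median-mean-smoothed DOY average over qualifying stations) →
Kriging → add the mean back → restore rate·altitude from the DEM.

RH combines the two surfaces through the Magnus formula (a = 17.271,
b = 237.7 °C). Uncapped RH exceeds 100% exactly when T_d > T; capping is
optional. The RH error combines the two Kriging errors by first-order
propagation with analytic partials, assuming T and T_d errors independent.

## LST gap filling

Per pixel (land only): noise removal → seasonal fit → day-of-year standard
deviation in a 31-day circular window with weights w(t) = 1 − |t/16|³
(w(0)=1, w(±15)≈0.176) → normalized departures z → iterative outlier loop
(strictly greater than 4 recomputed standard deviations per pass, until a
pass removes nothing; values removed here are re-estimated like missing
ones) → empirical autocorrelation from valid same-pixel pairs.

The autocorrelation is fitted as ρ(τ) = c·τ^(−α) on lags 1..(first
negative lag − 1), by least squares *on the linear scale* with c bounded
by 1 — a log-log line fit systematically overshoots ρ(1) for AR-like decay
and can exceed 1, destabilizing the solve. ρ(0) is 1 by definition; the
power law applies only to τ ≥ 1. Pixels with fewer than 50 lag-1 pairs,
non-positive ρ̂(1), or a failed fit skip temporal Kriging and keep full
variance (E = 1).

Temporal Kriging uses donors within max_lag days of the missing time. A
fitted power law need not be positive definite on integer-lag grids, so
the correlation matrix is inverted with a truncated pseudo-inverse
(relative eigenvalue cutoff 10⁻²): this confines the solve to the
well-determined eigenspace and keeps weights bounded; the remaining
variance fraction E = 1 − c₀ᵀw is clamped to [0, 1].

Each missing value becomes z = (1 − E)·G + E·A_avg with A_avg the mean
valid departure over the region (whole grid by default) that calendar day
(0 if none), then LST = MEAN + STD·z with the pixel's day-of-year MEAN and
STD; its variance is E·STD². Filled z is a convex combination, so
|z| ≤ max(|G|, |A_avg|). Observed values that survive the outlier loop
pass through untouched; a cube with no missing values (and no 4σ
departures) comes back identical.

Pathological pixels (quality rules above, negated) get MEAN/STD from valid
8-neighbours, filled iteratively most-connected-first (row-major ties),
with completed pixels immediately usable as donors; isolated islands copy
the nearest valid land pixel (first in row-major order on ties).
8-connectivity reduces island frequency relative to 4. Connected
pathological regions wider than 3 pixels (configurable) are filled with
the regional land average and flagged `regional_fallback` — or abort the
run with the offending region listed when the fallback is disabled; this
is the failure mode of persistently overcast regions (e.g. monsoon
seasons), which no neighbour-based completion can fix.

## Rainfall

Missing cells become 0 mm/day and values above 300 mm/day are capped, both
flagged, *before* bilinear interpolation from coarse cell centres to the
target grid — so interpolation never propagates missingness and output
stays within [0, 300]. Flags are transferred by nearest neighbour. A dry
day is rain ≤ 0 mm/day after preprocessing (threshold configurable; no
trace threshold by default). Diagnostics: per-pixel longest dry spell over
the record, and monthly mean daily rainfall across years. Spatially
averaging member pixels can only shorten the zero-threshold dry spell —
the mechanism by which gauge-interpolated products under-report droughts.

## Cross-validation

Leave-one-station-out: variograms, seasonal models, lapse rates and
regional means are fitted once on the full network and reused across folds
(`strict_loo` refits). The "climate" at a held-out temperature station is
its own fitted seasonal curve — the densest local normal available without
an external raster; this isolates the Kriging error from climate-layer
bias, which is why synthetic LOO residuals are near-perfectly calibrated
while real-world runs against an external normal would show its bias too.

Error summaries per station: bias, MAE, RMSE, and the 95th-percentile
absolute error (linear interpolation between order statistics — the rule
matters at small n). 10-day aggregation averages predictions and truths
within calendar-aligned blocks (Jan 1 anchored, ≥ 3 records per block) and
differences the block means. Calibration compares quantiles
(2.5/25/50/75/97.5%) of standardized residuals u = (pred − truth)/err with
standard-normal quantiles; zero-error records with nonzero residuals are
excluded and counted.

## Synthetic data = study conditions

Defaults emulate the island-scale study setting: 26 stations uniform over
a 13.5° × 7.3° box, 30 years daily, anomalies from a Gaussian random field
with C(d) = sill·2^(−d/λ) (sill 4 °C², λ 150 km, nugget 0) via Cholesky,
independent across days (temporal correlation is exercised separately by
the LST generator); seasonal truth 22 °C mean with 4 °C annual amplitude;
dew-point lapse −6 °C/km against a deterministic plateau-and-slope
altitude model; 10% of station-days deleted at random. The LST cube is
20×20 pixels × 3 years with AR(1) departures (φ = 0.7), mild day-of-year
scale modulation, 15% random missingness plus elliptical cloud blobs on
70% of days (~40% missing overall). Rainfall is a per-cell two-state
Markov chain (stationary wet fraction 0.3, persistence 0.5) coupled
through a Gaussian copula to a shared daily forcing, gamma amounts
(shape 0.8, scale 12 mm), 1% missing cells and rare >300 mm/day extremes.

Every generator is a pure function of the seeded config, and truth records
retain all generating parameters. What the passing tests show: parameter
recovery, calibration and gap-filling skill *under the assumed models*
(Gaussian fields, isotropy, AR(1), MCAR-ish missingness). What they do not
show: behaviour under real-world non-Gaussian tails (observed residual
tails are wider than Gaussian), cloud-correlated missingness, instrument
drift, anisotropy, or climate-layer bias — on real data the cross-validated
bias largely reflects the external climate normal, not the Kriging.

## Problem sizes and numerical choices

Routine tests use reduced sizes (10 stations × 5 years; 6×6 LST cubes);
the full study-condition checks (26 × 30 years variogram recovery, ≥ 5000
LOO records, 20×20×3yr LST fill) run in the acceptance-oriented tests and
script in a few minutes on one CPU. Key tolerances: variogram fit bounds
sill, λ > 0; outlier-loop comparison strict (>); percentile rule type-7;
temporal-solve eigenvalue cutoff 10⁻²; Kriging variance floored at 0.
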