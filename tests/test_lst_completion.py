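import numpy as np
import pytest

from vectorclim.lst_completion import (
    ACFModel,
    DegeneratePixelError,
    GridTimeSeries,
    PathologicalRegionError,
    PixelClimatology,
    SOURCE_NEIGHBOR,
    SOURCE_REGIONAL,
    blend_and_restore,
    classify_pathological,
    complete_pathological,
    empirical_acf,
    fill_grid,
    fit_acf,
    normalize_departures,
    outlier_loop,
    pixel_seasonal_stats,
    temporal_krige,
    window_weights,
    PROV_FILLED,
)
from vectorclim.harmonics import SeasonalModel

from conftest import daily_dates


def _ar1(n, phi, rng):
    x = np.empty(n)
    x[0] = rng.standard_normal()
    eps = rng.standard_normal(n) * np.sqrt(1 - phi ** 2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return x


class TestWindowWeights:
    def test_printed_weight_values(self):
        w = window_weights()
        assert len(w) == 31
        assert w[15] == 1.0  # t = 0
        assert w[0] == pytest.approx(1 - (15 / 16) ** 3)  # t = -15, ~0.176
        assert w[-1] == pytest.approx(1 - (15 / 16) ** 3)


class TestPixelSeasonalStats:
    def test_iid_noise_recovers_flat_std(self):
        rng = np.random.default_rng(1)
        dates = daily_dates("2003-01-01", 9 * 365)
        t = dates.astype(float)
        values = 25 + 3 * np.cos(2 * np.pi * t / 365.25) \
            + 2.0 * rng.standard_normal(len(t))
        model, doy_std = pixel_seasonal_stats(dates, values,
                                              np.ones(len(t), bool))
        assert np.all(np.abs(doy_std - 2.0) < 0.2)
        assert model.amplitude(1) == pytest.approx(3.0, abs=0.1)

    def test_constant_anomalies_flagged_degenerate(self):
        dates = daily_dates("2003-01-01", 800)
        with pytest.raises(DegeneratePixelError):
            pixel_seasonal_stats(dates, np.full(800, 20.0),
                                 np.ones(800, bool))


class TestNormalizeDepartures:
    def _setup(self):
        model = SeasonalModel(mean=20.0, cos_amp=[0, 0, 0], sin_amp=[0, 0, 0])
        dates = daily_dates("2003-01-01", 365)
        return model, dates

    def test_on_curve_gives_zero(self):
        model, dates = self._setup()
        z = normalize_departures(dates, np.full(365, 20.0), model,
                                 np.full(365, 2.0))
        np.testing.assert_allclose(z, 0.0)

    def test_doubling_std_halves_z(self):
        model, dates = self._setup()
        v = np.full(365, 24.0)
        z1 = normalize_departures(dates, v, model, np.full(365, 2.0))
        z2 = normalize_departures(dates, v, model, np.full(365, 4.0))
        np.testing.assert_allclose(z1, 2 * z2)

    def test_seeded_input_near_standard(self):
        rng = np.random.default_rng(3)
        dates = daily_dates("2003-01-01", 3 * 365)
        t = dates.astype(float)
        values = 25 + 3 * np.cos(2 * np.pi * t / 365.25) \
            + 1.5 * rng.standard_normal(len(t))
        model, doy_std = pixel_seasonal_stats(dates, values,
                                              np.ones(len(t), bool))
        z = normalize_departures(dates, values, model, doy_std)
        assert abs(np.nanmean(z)) < 0.05
        assert 0.9 < np.nanstd(z) < 1.1


class TestOutlierLoop:
    def test_single_injected_outlier_removed(self):
        rng = np.random.default_rng(11)
        z = rng.standard_normal(10000)
        z[1234] = 8.0
        cleaned, removed = outlier_loop(z)
        assert removed == 1
        assert np.isnan(cleaned[1234])

    def test_nothing_within_three_sigma_removed(self):
        z = np.clip(np.random.default_rng(0).standard_normal(500), -3, 3)
        _, removed = outlier_loop(z)
        assert removed == 0

    def test_second_outlier_exposed_after_first(self):
        # the big outlier inflates s; once removed, the smaller one emerges
        rng = np.random.default_rng(5)
        z = rng.standard_normal(200) * 0.5
        z[10] = 60.0
        z[20] = 12.0
        m0, s0 = z.mean(), z.std()
        assert abs(z[20] - m0) < 4 * s0  # hidden on the first pass
        cleaned, removed = outlier_loop(z)
        assert removed == 2
        assert np.isnan(cleaned[10]) and np.isnan(cleaned[20])

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            outlier_loop(np.ones(5))


class TestClassifyPathological:
    def test_empty_pixel(self):
        dates = daily_dates("2003-01-01", 100)
        assert classify_pathological(dates, np.zeros(100, bool))

    def test_dense_pixel_ok(self):
        dates = daily_dates("2003-01-01", 730)
        assert not classify_pathological(dates, np.ones(730, bool))

    def test_mirrors_station_thresholds(self):
        from vectorclim._dates import day_of_year_365

        n = 365 * 4
        dates = daily_dates("2001-01-01", n)
        doys = day_of_year_365(dates)
        # 31-day DOY gap -> pathological; 30-day gap -> fine
        assert classify_pathological(dates, ~((doys >= 100) & (doys <= 130)))
        assert not classify_pathological(dates, ~((doys >= 100) & (doys <= 129)))


class TestFitACF:
    def test_ar1_recovery(self):
        rng = np.random.default_rng(21)
        z = _ar1(3000, 0.7, rng)
        acf = fit_acf(z)
        assert acf is not None
        assert acf.max_lag >= 5
        assert acf.rho(1) == pytest.approx(0.7, abs=0.1)

    def test_white_noise_often_rejected(self):
        n_none = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal(300)
            if fit_acf(z) is None:
                n_none += 1
        assert n_none >= 40

    def test_exact_power_law_recovery(self):
        # construct a series whose empirical ACF is an exact power law by
        # fitting directly to synthetic correlation values
        lags = np.arange(1.0, 8.0)
        rho = 0.8 * lags ** (-1.0)
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(lambda t, c, a: c * t ** (-a), lags, rho,
                            p0=[0.5, 0.5], bounds=([1e-6, 0], [1, 10]))
        assert popt[0] == pytest.approx(0.8, abs=1e-2)
        assert popt[1] == pytest.approx(1.0, abs=1e-2)
        # and the model object clamps sensibly
        m = ACFModel(coeff=0.8, exponent=1.0, max_lag=7)
        assert m.rho(1) == pytest.approx(0.8)
        assert m.rho(4) == pytest.approx(0.2)

    def test_insufficient_pairs_returns_none(self):
        assert fit_acf(np.ones(30)) is None


class TestTemporalKrige:
    def test_single_donor_closed_form(self):
        acf = ACFModel(coeff=0.7, exponent=0.0, max_lag=1)
        z = np.array([np.nan, 2.0, np.nan])
        G, E = temporal_krige(z, np.array([0, 1, 2]), 0, acf)
        assert G == pytest.approx(0.7 * 2.0)
        assert E == pytest.approx(1 - 0.49)

    def test_no_donors_full_variance(self):
        acf = ACFModel(coeff=0.7, exponent=1.0, max_lag=2)
        z = np.array([np.nan, np.nan, np.nan, 1.0])
        G, E = temporal_krige(z, np.array([0, 1, 2, 10]), 0, acf)
        assert (G, E) == (0.0, 1.0)

    def test_donor_at_missing_time_asserts(self):
        acf = ACFModel(coeff=0.7, exponent=1.0, max_lag=3)
        z = np.array([1.0, 2.0])
        with pytest.raises(AssertionError):
            temporal_krige(z, np.array([0, 1]), 0, acf)


class TestBlendAndRestore:
    @pytest.mark.parametrize("G,E,a_avg,mean,std,expected", [
        (1.5, 0.0, -0.5, 30.0, 2.0, 33.0),   # E=0: pure temporal guess
        (1.5, 1.0, -0.5, 30.0, 2.0, 29.0),   # E=1: pure regional mean
        (1.0, 0.4, -0.5, 30.0, 2.0, 30.8),   # stated arithmetic example
    ])
    def test_blend_values(self, G, E, a_avg, mean, std, expected):
        assert blend_and_restore(G, E, a_avg, mean, std) == pytest.approx(expected)

    def test_convexity(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            G, a = rng.standard_normal(2)
            E = rng.random()
            z = (blend_and_restore(G, E, a, 0.0, 1.0))
            assert abs(z) <= max(abs(G), abs(a)) + 1e-12


class TestCompletePathological:
    def _clim(self, shape=(4, 4)):
        mean = np.ones((365,) + shape)
        std = np.ones((365,) + shape)
        return mean, std

    def test_single_pixel_eight_neighbor_mean(self):
        mean, std = self._clim()
        mean[:, 1, 1] = np.nan
        for (y, x), v in zip([(0, 0), (0, 1), (0, 2), (1, 0), (1, 2),
                              (2, 0), (2, 1), (2, 2)], range(8)):
            mean[:, y, x] = float(v)
        patho = np.zeros((4, 4), bool)
        patho[1, 1] = True
        out = complete_pathological(
            PixelClimatology(mean, std, np.zeros((4, 4), int)), patho)
        assert out.mean[0, 1, 1] == pytest.approx(np.mean(range(8)))
        assert out.source[1, 1] == SOURCE_NEIGHBOR

    def test_edge_pair_ordering(self):
        mean, std = self._clim()
        patho = np.zeros((4, 4), bool)
        patho[0, 0] = patho[0, 1] = True
        mean[:, 0, 0] = np.nan
        mean[:, 0, 1] = np.nan
        mean[:, 0, 2] = 2.0
        mean[:, 1, 0] = 4.0
        mean[:, 1, 1] = 5.0
        mean[:, 1, 2] = 6.0
        out = complete_pathological(
            PixelClimatology(mean, std, np.zeros((4, 4), int)), patho)
        # (0,1) has 4 valid neighbours, fills first as mean(2,4,5,6)=4.25;
        # (0,0) then uses (0,1)=4.25 with (1,0),(1,1)
        assert out.mean[0, 0, 1] == pytest.approx(4.25)
        assert out.mean[0, 0, 0] == pytest.approx((4.25 + 4.0 + 5.0) / 3)

    def test_isolated_island_takes_nearest_land(self):
        land = np.zeros((5, 5), bool)
        land[0, 0] = land[4, 3] = land[4, 4] = True
        mean = np.full((365, 5, 5), np.nan)
        std = np.full((365, 5, 5), np.nan)
        mean[:, 4, 3] = 5.0
        std[:, 4, 3] = 1.0
        mean[:, 4, 4] = 7.0
        std[:, 4, 4] = 1.0
        patho = np.zeros((5, 5), bool)
        patho[0, 0] = True
        out = complete_pathological(
            PixelClimatology(mean, std, np.zeros((5, 5), int)), patho, land)
        assert out.mean[0, 0, 0] == 5.0  # (4,3) is nearer than (4,4)

    def test_oversized_region_raises_or_falls_back(self):
        mean, std = self._clim((6, 6))
        patho = np.zeros((6, 6), bool)
        patho[1:5, 1:5] = True
        mean[:, patho] = np.nan
        clim = PixelClimatology(mean, std, np.zeros((6, 6), int))
        with pytest.raises(PathologicalRegionError, match="region"):
            complete_pathological(clim, patho, allow_regional_fallback=False)
        out = complete_pathological(clim, patho)
        assert np.all(out.source[patho] == SOURCE_REGIONAL)
        assert np.all(np.isfinite(out.mean))


@pytest.fixture(scope="module")
def small_cube():
    from vectorclim.synthetic import SynthConfig, gen_lst_cube

    cfg = SynthConfig(seed=19, lst_shape=(6, 6), lst_years=3,
                      lst_missing_rate=0.12, lst_blob_prob=0.4,
                      lst_blob_radius_px=(1.0, 2.5))
    return gen_lst_cube(cfg)


class TestFillGrid:

    def test_no_missing_passthrough(self):
        from vectorclim.synthetic import SynthConfig, gen_lst_cube

        cfg = SynthConfig(seed=23, lst_shape=(4, 4), lst_years=3,
                          lst_missing_rate=0.0, lst_blob_prob=0.0)
        grid, truth = gen_lst_cube(cfg)
        res = fill_grid(grid)
        observed = res.provenance == 0
        np.testing.assert_array_equal(res.grid.values[observed],
                                      grid.values[observed])
        # at most a handful of extreme observations get re-estimated
        assert (res.provenance == PROV_FILLED).mean() < 0.001

    def test_fill_beats_climatology_and_is_convex(self, small_cube):
        grid, truth = small_cube
        res = fill_grid(grid)
        filled = res.provenance == PROV_FILLED
        assert filled.any()
        rmse_fill = np.sqrt(np.mean((res.grid.values[filled] - truth[filled]) ** 2))
        doys = grid.doy()
        clim = res.climatology.mean[doys - 1]
        rmse_clim = np.sqrt(np.mean((clim[filled] - truth[filled]) ** 2))
        assert rmse_fill < rmse_clim
        assert np.all(np.isfinite(res.grid.values[:, grid.land_mask]))
        assert np.all(res.variance[filled] >= 0)

    def test_abort_on_oversized_pathological_region(self):
        # a quadrant that is almost always cloudy is unfixable by neighbours
        from vectorclim.synthetic import SynthConfig, gen_lst_cube

        cfg = SynthConfig(seed=29, lst_shape=(8, 8), lst_years=3,
                          lst_missing_rate=0.05, lst_blob_prob=0.0)
        grid, _ = gen_lst_cube(cfg)
        grid.valid[:, 0:6, 0:6] = False
        grid.values[:, 0:6, 0:6] = np.nan
        with pytest.raises(PathologicalRegionError):
            fill_grid(grid, allow_regional_fallback=False)
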