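import numpy as np
import pytest

from vectorclim.geostat import (
    SimpleKriging,
    SingularCovarianceError,
    VariogramFitError,
    covariance_model,
    empirical_semivariance,
    fit_variogram,
    fit_variogram_doy,
    haversine_km,
    median_mean_smooth,
    simple_krige,
    variogram_model,
)
from vectorclim.harmonics import fit_seasonal, subtract_seasonal

from conftest import daily_dates


def _anoms(stations):
    out = []
    for s in stations:
        m = fit_seasonal(s.dates, s.values, s.valid)
        out.append((s, subtract_seasonal(s.dates, s.values, m, s.valid)))
    return out


class TestEmpiricalSemivariance:
    def test_single_pair_half_squared_difference(self, make_station):
        # two stations ~100 km apart with constant anomalies +1 / -1
        a = make_station("A", lat=-20.0, lon=46.0, n=365,
                         values=np.full(365, 1.0))
        b = make_station("B", lat=-20.0, lon=46.0 + 100.0 / (111.32 * np.cos(np.radians(20.0))),
                         n=365, values=np.full(365, -1.0))
        d, g = empirical_semivariance([(a, np.ones(365)), (b, -np.ones(365))], doy=50)
        assert len(d) == 1
        assert g[0] == pytest.approx(0.5 * 2.0 ** 2)
        assert d[0] == pytest.approx(100.0, rel=0.01)

    def test_half_factor_switch(self, make_station):
        a = make_station("A", n=365)
        b = make_station("B", lat=-21.0, n=365)
        pairs = [(a, np.ones(365)), (b, -np.ones(365))]
        _, g_half = empirical_semivariance(pairs, doy=10, half=True)
        _, g_full = empirical_semivariance(pairs, doy=10, half=False)
        assert g_full[0] == pytest.approx(2 * g_half[0])

    def test_no_self_pairs_and_pair_count(self, make_station):
        # 3 stations, 2 complete years -> 3 pairs x 2 years = 6
        sts = [make_station(f"S{i}", lat=-20.0 - i, n=730,
                            values=np.arange(730, dtype=float))
               for i in range(3)]
        pairs = [(s, s.values.copy()) for s in sts]
        d, g = empirical_semivariance(pairs, doy=100)
        assert len(d) == 6
        assert np.all(d > 0)  # no zero-distance self pairs


class TestFitVariogram:
    def test_noise_free_recovery(self):
        # pairs exactly on the curve, placed at bin centres so binning is lossless
        centers = np.arange(12.5, 600, 25.0)
        d = np.repeat(centers, 20)
        g = variogram_model(d, 4.0, 100.0)
        (sill, lam, nug), diag = fit_variogram(d, g)
        assert sill == pytest.approx(4.0, rel=1e-6)
        assert lam == pytest.approx(100.0, rel=1e-6)
        assert nug == 0.0
        assert diag["resid_rms"] < 1e-8

    def test_single_distance_raises(self):
        d = np.full(100, 50.0)
        g = np.full(100, 2.0)
        with pytest.raises(VariogramFitError):
            fit_variogram(d, g)

    def test_correlation_halves_at_lambda(self):
        # the model is parameterized so C(lam)/C(0) = 1/2 exactly
        assert covariance_model(150.0, 4.0, 150.0) == pytest.approx(2.0)
        assert variogram_model(150.0, 4.0, 150.0) == pytest.approx(2.0)


class TestMedianMeanSmooth:
    def test_constant_preserved(self):
        np.testing.assert_allclose(median_mean_smooth(np.full(365, 3.3)),
                                   np.full(365, 3.3))

    def test_single_spike_killed(self):
        x = np.full(365, 10.0)
        x[49] = 100.0
        np.testing.assert_allclose(median_mean_smooth(x), np.full(365, 10.0),
                                   atol=1e-9)

    def test_circular_rotation_equivariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(365)
        x[364] = 50.0
        out = median_mean_smooth(x)
        out_rot = median_mean_smooth(np.roll(x, 100))
        np.testing.assert_allclose(np.roll(out, 100), out_rot, atol=1e-12)

    def test_nan_bins_filled(self):
        x = np.full(365, 2.0)
        x[100:105] = np.nan
        out = median_mean_smooth(x)
        assert np.all(np.isfinite(out))
        np.testing.assert_allclose(out, 2.0)


class TestSimpleKriging:
    def _three_stations(self):
        X = np.array([[-20.0, 46.0], [-21.0, 47.0], [-19.5, 45.0]])
        y = np.array([1.0, -0.5, 2.0])
        return X, y

    def test_exactness_at_stations_nugget_zero(self):
        X, y = self._three_stations()
        k = SimpleKriging(sill=4.0, half_dist=150.0).fit(X, y)
        pred, std = k.predict(X, return_std=True)
        np.testing.assert_allclose(pred, y, atol=1e-8)
        np.testing.assert_allclose(std, 0.0, atol=1e-6)

    def test_far_target_reverts_to_mean_and_sqrt_sill(self):
        X, y = self._three_stations()
        k = SimpleKriging(sill=4.0, half_dist=150.0).fit(X, y)
        pred, std = k.predict([[40.0, 120.0]], return_std=True)  # ~50 lam away
        assert abs(pred[0]) < 1e-3
        assert std[0] == pytest.approx(np.sqrt(4.0), abs=1e-3)

    def test_symmetric_equidistant_stations(self):
        X = np.array([[-20.0, 45.0], [-20.0, 47.0]])
        a = 1.4
        k = SimpleKriging(sill=4.0, half_dist=150.0).fit(X, np.array([a, a]))
        pred = k.predict([[-20.0, 46.0]])
        assert 0.0 < pred[0] < a

    def test_linearity_in_observations(self):
        X, y = self._three_stations()
        k1 = SimpleKriging(sill=4.0, half_dist=150.0).fit(X, y)
        k2 = SimpleKriging(sill=4.0, half_dist=150.0).fit(X, 2.5 * y)
        tgt = [[-20.5, 46.5]]
        assert k2.predict(tgt)[0] == pytest.approx(2.5 * k1.predict(tgt)[0])

    def test_duplicate_stations_nugget_zero_raises(self):
        X = np.array([[-20.0, 46.0], [-20.0, 46.0]])
        with pytest.raises(SingularCovarianceError, match="nugget"):
            SimpleKriging(sill=4.0, half_dist=150.0).fit(X, np.array([1.0, 2.0]))
        # a nugget makes the same configuration solvable
        SimpleKriging(sill=4.0, half_dist=150.0, nugget=0.5).fit(
            X, np.array([1.0, 2.0])
        )

    def test_variance_monotone_as_station_recedes(self):
        var_prev = -1.0
        for lon in (46.1, 46.5, 47.0, 48.0, 50.0):
            k = SimpleKriging(sill=4.0, half_dist=150.0).fit(
                np.array([[-20.0, lon]]), np.array([1.0])
            )
            _, std = k.predict([[-20.0, 46.0]], return_std=True)
            assert std[0] > var_prev
            assert std[0] <= np.sqrt(4.0) + 1e-12
            var_prev = std[0]

    def test_grid_prediction_convergence_with_density(self):
        # denser observations of a smooth field reduce grid RMSE
        rng = np.random.default_rng(9)

        def field(lat, lon):
            return np.sin(lat / 2.0) + np.cos(lon / 2.0)

        lats = np.linspace(-22, -18, 8)
        lons = np.linspace(44, 48, 8)
        LA, LO = np.meshgrid(lats, lons, indexing="ij")
        rmses = []
        for n in (10, 40, 160):
            slat = rng.uniform(-22, -18, n)
            slon = rng.uniform(44, 48, n)
            fld = simple_krige(np.column_stack([slat, slon]),
                               field(slat, slon), lats, lons,
                               (4.0, 150.0, 0.0))
            rmses.append(np.sqrt(np.mean((fld.prediction - field(LA, LO)) ** 2)))
        assert rmses[2] < rmses[1] < rmses[0]


class TestVariogramDOYPipeline:
    def test_recovery_on_small_network(self, small_network):
        stations, truth, cfg = small_network
        vg = fit_variogram_doy(_anoms(stations))
        assert np.all(vg.sill > 0)
        assert np.all(vg.half_dist > 0)
        # small network: generous sanity band around the generating truth
        assert np.median(vg.sill) == pytest.approx(cfg.sill, rel=0.4)
        assert np.median(vg.half_dist) == pytest.approx(cfg.half_dist_km, rel=0.6)

    def test_haversine_known_distance(self):
        # one degree of latitude is ~111.2 km
        assert haversine_km(-20.0, 46.0, -21.0, 46.0) == pytest.approx(111.2, abs=1.0)
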