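import numpy as np
import pandas as pd
import pytest

from vectorclim.station_io import StationSeries


def daily_dates(start: str, n: int) -> np.ndarray:
    return pd.date_range(start, periods=n, freq="D").to_numpy("datetime64[D]")


@pytest.fixture
def make_station():
    """Factory for small hand-made stations."""

    def _make(station_id="S0", lat=-20.0, lon=46.0, altitude=0.0,
              start="2000-01-01", n=730, values=None, valid=None):
        dates = daily_dates(start, n)
        if values is None:
            values = np.full(n, 20.0)
        values = np.asarray(values, dtype=float)
        if valid is None:
            valid = np.isfinite(values)
        return StationSeries(station_id, lat, lon, altitude, dates,
                             np.where(valid, values, np.nan), valid)

    return _make


@pytest.fixture(scope="session")
def small_network():
    """10-station, 5-year network with known variogram truth (fast)."""
    from vectorclim.synthetic import SynthConfig, gen_station_network

    cfg = SynthConfig(seed=1234, n_stations=10, n_years=5)
    stations, truth = gen_station_network(cfg)
    return stations, truth, cfg


@pytest.fixture(scope="session")
def madagascar_network():
    """Full study-condition network: 26 stations x 30 years, sill 4, lam 150."""
    from vectorclim.synthetic import SynthConfig, gen_station_network

    cfg = SynthConfig(seed=42)
    stations, truth = gen_station_network(cfg)
    return stations, truth, cfg
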