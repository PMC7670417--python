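import numpy as np
import pytest

from bioclimind import (
    DailyClimateSeries,
    SyntheticClimateConfig,
    constant_config,
    generate_daily_climate,
)


@pytest.fixture(scope="session")
def constant_series():
    """Noiseless constant climate: tg=10, tx=15, tn=5, p=2, 360-day, 5 years."""
    return generate_daily_climate(constant_config())


@pytest.fixture(scope="session")
def noisy_series():
    """A small stochastic multi-latitude grid, no-leap calendar, 6 years."""
    cfg = SyntheticClimateConfig(years=range(2000, 2006), seed=7)
    return generate_daily_climate(cfg)


def random_cell_series(rng, calendar, n_years=4, lat=None):
    """One-cell series with randomized seasonal structure and noise."""
    lat = float(rng.uniform(-80, 80)) if lat is None else lat
    cfg = SyntheticClimateConfig(
        lat=np.array([lat]), lon=np.array([0.0]),
        years=range(2000, 2000 + n_years), calendar=calendar,
        tg_mean=float(rng.uniform(-12, 28)),
        tg_amplitude=float(rng.uniform(0, 22)),
        diurnal_range=float(rng.uniform(2, 14)),
        precip_annual=float(rng.uniform(50, 2500)),
        precip_seasonality=float(rng.uniform(0, 1)),
        temp_noise_sd=float(rng.uniform(0, 3)),
        precip_stochastic=True,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return generate_daily_climate(cfg)


def cell_to_daily_dicts(series: DailyClimateSeries, iy=0, ix=0):
    """Flatten one grid cell of a series into the oracle's per-day dicts."""
    return [
        {"tg": float(series.tg[t, iy, ix]), "tx": float(series.tx[t, iy, ix]),
         "tn": float(series.tn[t, iy, ix]), "p": float(series.p[t, iy, ix])}
        for t in range(series.tg.shape[0])
    ]
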