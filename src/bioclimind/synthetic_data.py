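"""Self-contained synthetic daily climate fixtures.

The generator produces physically coherent daily series with the structure
the indicator engine assumes: a latitude-dependent sinusoidal annual cycle
of mean temperature (phase flipped between hemispheres, warmest around
mid-July north of the equator and mid-January south of it), a fixed diurnal
range splitting Tx/Tn symmetrically around Tg, and non-negative
precipitation whose seasonal intensity follows the same annual phase.
Optional noise: Gaussian perturbations on temperature, exponential daily
intensities on precipitation (non-negative by construction, giving distinct
wettest/driest months).  A single integer seed makes every fixture
bit-reproducible.

It emulates the gross features of bias-corrected global forcing at coarse
resolution; it makes no attempt at spatial correlation, weather persistence
or extreme-value statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import temporal_core as tc
from .ensemble import EnsembleStack
from .indicators import IndicatorField, compute_indicator
from .pet import month_mid_doy
from .temporal_core import DailyClimateSeries


def _as_lat_function(value) -> Callable[[np.ndarray], np.ndarray]:
    if callable(value):
        return value
    return lambda lat: np.full_like(np.asarray(lat, dtype=float), float(value))


def default_tg_mean(lat: np.ndarray) -> np.ndarray:
    """Annual-mean temperature profile: ~27 degC at the equator, polar frost."""
    lat = np.asarray(lat, dtype=float)
    return 27.0 - 42.0 * (lat / 90.0) ** 2


def default_tg_amplitude(lat: np.ndarray) -> np.ndarray:
    """Seasonal half-amplitude: ~2 degC tropics, ~20 degC poleward."""
    lat = np.asarray(lat, dtype=float)
    return 2.0 + 18.0 * np.abs(lat) / 90.0


def default_precip_annual(lat: np.ndarray) -> np.ndarray:
    """Annual precipitation: wet tropics (~2000 mm) drying toward the poles."""
    lat = np.asarray(lat, dtype=float)
    return 200.0 + 1800.0 * np.cos(np.deg2rad(lat)) ** 2


@dataclass
class SyntheticClimateConfig:
    """Parameters of the synthetic climate generator.

    ``tg_mean``, ``tg_amplitude`` and ``precip_annual`` accept either a
    scalar or a callable of latitude (degrees north).  ``temp_noise_sd`` is
    the SD of additive Gaussian noise on daily Tg (degC); setting
    ``precip_stochastic`` draws daily precipitation as exponential
    intensities around the seasonal mean instead of the mean itself.
    """

    lat: np.ndarray = field(default_factory=lambda: np.array([-75., -45., -15., 15., 45., 75.]))
    lon: np.ndarray = field(default_factory=lambda: np.linspace(-157.5, 157.5, 8))
    years: Sequence[int] = (2000, 2001, 2002, 2003, 2004, 2005, 2006, 2007, 2008, 2009)
    calendar: str = "noleap"
    tg_mean: object = default_tg_mean
    tg_amplitude: object = default_tg_amplitude
    diurnal_range: float = 8.0
    precip_annual: object = default_precip_annual
    precip_seasonality: float = 0.5
    temp_noise_sd: float = 1.0
    precip_stochastic: bool = True
    seed: int = 0

    def __post_init__(self):
        self.lat = np.atleast_1d(np.asarray(self.lat, dtype=float))
        self.lon = np.atleast_1d(np.asarray(self.lon, dtype=float))
        self.years = np.asarray(list(self.years), dtype=int)
        self.calendar = tc.normalize_calendar(self.calendar)
        if self.years.size == 0:
            raise ValueError("need at least one year")
        if not 0.0 <= self.precip_seasonality <= 1.0:
            raise ValueError("precip_seasonality must be within [0, 1]")


def constant_config(tg=10.0, tx=15.0, tn=5.0, p=2.0, calendar="360_day",
                    years=range(2000, 2005), lat=(45.0,), lon=(0.0,)) -> SyntheticClimateConfig:
    """A noiseless constant-climate configuration (the analytic test case)."""
    return SyntheticClimateConfig(
        lat=np.asarray(lat, float), lon=np.asarray(lon, float), years=list(years),
        calendar=calendar, tg_mean=tg, tg_amplitude=0.0,
        diurnal_range=float(tx - tn),
        precip_annual=lambda la: np.full_like(np.asarray(la, float),
                                              p * tc.days_in_year(2001, calendar)),
        precip_seasonality=0.0, temp_noise_sd=0.0, precip_stochastic=False, seed=0,
    )


def generate_daily_climate(config: SyntheticClimateConfig) -> DailyClimateSeries:
    """Generate a daily series under the given configuration.

    Deterministic for a fixed seed.  The seasonal temperature cycle is
    ``tg_mean + A * cos(2*pi*(d - d_peak)/L)`` with ``d_peak`` at mid-July
    (mid-January in the Southern Hemisphere); because the cosine is sampled
    uniformly over whole years its annual mean vanishes exactly, so the
    noiseless annual-mean temperature recovers ``tg_mean`` to rounding.
    Daily precipitation is the seasonal mean intensity (expected annual
    total = ``precip_annual``), optionally multiplied by unit-mean
    exponential noise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lat, lon = cfg.lat, cfg.lon
    h, w = lat.size, lon.size
    tg_mean = _as_lat_function(cfg.tg_mean)(lat)[:, None] * np.ones((1, w))
    amp = _as_lat_function(cfg.tg_amplitude)(lat)[:, None] * np.ones((1, w))
    p_annual = _as_lat_function(cfg.precip_annual)(lat)[:, None] * np.ones((1, w))

    blocks_tg, blocks_p = [], []
    south = (lat < 0.0)[:, None] * np.ones((1, w), dtype=bool)
    for y in cfg.years:
        yl = tc.days_in_year(int(y), cfg.calendar)
        d = np.arange(yl, dtype=float)
        peak = month_mid_doy(int(y), cfg.calendar)[6]  # mid-July
        phase = 2.0 * np.pi * (d[:, None, None] - peak) / yl
        # half-year phase flip south of the equator
        phase = np.where(south[None], phase + np.pi, phase)
        cyc = np.cos(phase)
        blocks_tg.append(tg_mean[None] + amp[None] * cyc)
        p_daily = p_annual[None] / yl * (1.0 + cfg.precip_seasonality * cyc)
        blocks_p.append(np.maximum(p_daily, 0.0))
    tg = np.concatenate(blocks_tg, axis=0)
    p = np.concatenate(blocks_p, axis=0)
    if cfg.temp_noise_sd > 0:
        tg = tg + rng.normal(0.0, cfg.temp_noise_sd, tg.shape)
    if cfg.precip_stochastic:
        p = p * rng.exponential(1.0, p.shape)
    half = cfg.diurnal_range / 2.0
    series = DailyClimateSeries(
        tg=tg, tx=tg + half, tn=tg - half, p=p,
        years=cfg.years, calendar=cfg.calendar, lat=lat, lon=lon,
    )
    series.validate()
    return series


def generate_ensemble_fixture(
    config: SyntheticClimateConfig,
    n_members: int,
    bio_code: int = 1,
    offsets: Sequence[float] | None = None,
    scales: Sequence[float] | None = None,
) -> EnsembleStack:
    """An ensemble stack with analytically known anomaly and spread.

    A reference indicator field is computed from the synthetic series; each
    member is ``scale * reference + offset``.  All offsets/scales defaulting
    to 0/1 gives zero anomaly and zero RSD.
    """
    if n_members < 2:
        raise ValueError("an ensemble needs at least 2 members")
    offsets = [0.0] * n_members if offsets is None else list(offsets)
    scales = [1.0] * n_members if scales is None else list(scales)
    if len(offsets) != n_members or len(scales) != n_members:
        raise ValueError("offsets/scales length must equal n_members")
    series = generate_daily_climate(config)
    reference = compute_indicator(bio_code, series)
    members = []
    for k, (off, sc) in enumerate(zip(offsets, scales)):
        members.append(IndicatorField(
            bio_code=bio_code, values=sc * reference.values + off,
            units=reference.units, period=reference.period,
            lat=reference.lat, lon=reference.lon,
            attrs=dict(reference.attrs, member=k),
        ))
    return EnsembleStack(members=members, reference=reference)
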