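"""Temperature-based potential evapotranspiration (Bio34, Bio35).

Two classical monthly formulations driven only by temperature and solar
geometry:

* **Hargreaves-Samani (1985)**:  ``PET = 0.0023 * Ra * (Tg + 17.8) * sqrt(TD)``
  in mm/day, where ``Ra`` is the extraterrestrial radiation expressed as
  evaporation-equivalent mm/day and ``TD`` the monthly mean diurnal range.
  Negative values of the ``(Tg + 17.8)`` factor are clamped to zero.

* **Thornthwaite (1948)**: ``PET = 16 * (10*Tm/I)**a * (N/12) * (days/30)``
  mm/month for months with mean temperature ``Tm > 0``; ``I`` is the annual
  heat index ``sum((Tm/5)**1.514)`` over positive months and ``a`` the usual
  cubic in ``I``.  ``N`` is the mid-month day length in hours.  The original
  formulation is used throughout (no hot-month extension above 26.5 degC).

Solar geometry (declination, sunset hour angle, day length, FAO-56
extraterrestrial radiation) is evaluated at the mid-point day of each
calendar month, calendar-aware so that 360-day model years stay internally
consistent.  Both PET indicators are annual totals averaged over the years
of the period; the heat index is computed per year, matching the
per-year-then-average pattern of every other indicator.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import temporal_core as tc
from .temporal_core import DailyClimateSeries, MonthlyTable

#: Solar constant, MJ m-2 min-1 (FAO-56).
SOLAR_CONSTANT = 0.0820
#: MJ m-2 day-1 -> evaporation-equivalent mm/day.
MJ_TO_MM = 0.408

#: Fraction of a cell's years that must be complete for the PET average.
MIN_VALID_YEAR_FRACTION = 0.8


def month_mid_doy(year: int, calendar: str) -> np.ndarray:
    """Day-of-year of each calendar month's midpoint (1-based, fractional)."""
    ml = tc.month_lengths(year, calendar).astype(float)
    ends = np.cumsum(ml)
    return ends - ml / 2.0


def _solar_angles(latitude, doy, year_length):
    """Solar declination and sunset hour angle at a fractional day of year."""
    lat_rad = np.deg2rad(np.asarray(latitude, dtype=float))
    frac = 2.0 * np.pi * np.asarray(doy, dtype=float) / year_length
    decl = 0.409 * np.sin(frac - 1.39)
    # cos(ws) outside [-1, 1] means polar day/night; clamp before arccos
    cos_ws = np.clip(-np.tan(lat_rad) * np.tan(decl), -1.0, 1.0)
    return lat_rad, decl, np.arccos(cos_ws), frac


def day_length(latitude, month: int, calendar: str = "standard", year: int = 2001) -> np.ndarray:
    """Mid-month day length in hours (0 at polar night, 24 at polar day)."""
    doy = month_mid_doy(year, calendar)[month - 1]
    yl = tc.days_in_year(year, calendar)
    _, _, ws, _ = _solar_angles(latitude, doy, yl)
    return 24.0 / np.pi * ws


def extraterrestrial_radiation(latitude, month: int, calendar: str = "standard",
                               year: int = 2001) -> np.ndarray:
    """Mid-month top-of-atmosphere radiation, evaporation-equivalent mm/day."""
    doy = month_mid_doy(year, calendar)[month - 1]
    yl = tc.days_in_year(year, calendar)
    lat_rad, decl, ws, frac = _solar_angles(latitude, doy, yl)
    dr = 1.0 + 0.033 * np.cos(frac)  # inverse relative Earth-Sun distance
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(lat_rad) * np.sin(decl)
        + np.cos(lat_rad) * np.cos(decl) * np.sin(ws)
    )
    return MJ_TO_MM * np.maximum(ra, 0.0)


def monthly_solar_table(latitude, year: int, calendar: str):
    """(Ra, N) for all 12 months; shapes ``(12,) + shape(latitude)``."""
    ra = np.stack([extraterrestrial_radiation(latitude, m, calendar, year) for m in range(1, 13)])
    n = np.stack([day_length(latitude, m, calendar, year) for m in range(1, 13)])
    return ra, n


def hargreaves_monthly(tg_month, td_month, ra, n_days):
    """Monthly Hargreaves-Samani PET total (mm/month).

    All arguments broadcast; ``td_month`` is the monthly mean diurnal range
    (degC) and ``ra`` the mm/day extraterrestrial radiation.  Negative
    ``tg + 17.8`` is clamped so PET is never negative.
    """
    td = np.maximum(np.asarray(td_month, dtype=float), 0.0)
    factor = np.maximum(np.asarray(tg_month, dtype=float) + 17.8, 0.0)
    return 0.0023 * np.asarray(ra) * factor * np.sqrt(td) * np.asarray(n_days)


def thornthwaite_year(tg_months, day_len, n_days):
    """Monthly Thornthwaite PET totals (mm/month) for one year.

    ``tg_months`` are the 12 monthly mean temperatures (leading axis 12);
    the heat index is that year's own.  Months with ``Tm <= 0`` contribute 0,
    and a year whose heat index is 0 has zero PET everywhere.
    """
    tm = np.asarray(tg_months, dtype=float)
    pos = tm > 0.0
    heat = np.where(pos, (np.maximum(tm, 0.0) / 5.0) ** 1.514, 0.0).sum(axis=0)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    with np.errstate(divide="ignore", invalid="ignore"):
        base = 16.0 * (10.0 * np.maximum(tm, 0.0) / heat) ** a
    pet = np.where(pos & (heat > 0), base, 0.0)
    pet = pet * (np.asarray(day_len) / 12.0) * (np.asarray(n_days) / 30.0)
    # propagate missing months (a missing month also poisons the heat index,
    # so the whole year drops out)
    return np.where(np.isnan(tm) | np.isnan(heat), np.nan, pet)


def _average_annual_totals(annual: np.ndarray) -> np.ndarray:
    """Mean of per-year totals, requiring >= 80% of years to be complete."""
    valid = np.isfinite(annual)
    frac = valid.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(annual, axis=0)
    return np.where(frac >= MIN_VALID_YEAR_FRACTION, mean, np.nan)


def _monthly_diurnal_range(series: DailyClimateSeries) -> np.ndarray:
    """Monthly mean of daily (tx - tn), shape (n_years, 12, h, w)."""
    td_series = DailyClimateSeries(
        tg=series.tx - series.tn, tx=series.tx - series.tn,
        tn=series.tx - series.tn, p=np.zeros_like(series.p),
        years=series.years, calendar=series.calendar,
        lat=series.lat, lon=series.lon,
        day_year=series.day_year, day_month=series.day_month,
    )
    return tc.aggregate_monthly(td_series).tg_mean


def pet_hargreaves_map(series: DailyClimateSeries, table: MonthlyTable | None = None) -> np.ndarray:
    """Bio34: mean over years of the annual Hargreaves-Samani PET sum."""
    if table is None:
        table = tc.aggregate_monthly(series)
    td = _monthly_diurnal_range(series)  # (ny, 12, h, w)
    lat2d = series.lat[:, None] * np.ones((1, series.lon.size))
    annual = np.empty((series.n_years,) + series.grid_shape)
    for i, y in enumerate(series.years):
        ra, _ = monthly_solar_table(lat2d, int(y), series.calendar)
        nd = tc.month_lengths(int(y), series.calendar)[:, None, None].astype(float)
        pet = hargreaves_monthly(table.tg_mean[i], td[i], ra, nd)
        annual[i] = pet.sum(axis=0)
    return _average_annual_totals(annual)


def pet_thornthwaite_map(series: DailyClimateSeries, table: MonthlyTable | None = None) -> np.ndarray:
    """Bio35: mean over years of the annual Thornthwaite PET sum."""
    if table is None:
        table = tc.aggregate_monthly(series)
    lat2d = series.lat[:, None] * np.ones((1, series.lon.size))
    annual = np.empty((series.n_years,) + series.grid_shape)
    for i, y in enumerate(series.years):
        _, n = monthly_solar_table(lat2d, int(y), series.calendar)
        nd = tc.month_lengths(int(y), series.calendar)[:, None, None].astype(float)
        pet = thornthwaite_year(table.tg_mean[i], n, nd)
        annual[i] = pet.sum(axis=0)
    return _average_annual_totals(annual)
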