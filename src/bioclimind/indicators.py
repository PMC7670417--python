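"""Bioclimatic indicators Bio1-Bio35 from daily climate series.

Each indicator is a single 2-D lat/lon map summarizing a multi-year period.
The family follows the WorldClim/ANUCLIM lineage for Bio1-Bio19 and adds
Rivas-Martinez, Kira, Ellenberg and continentality indices (Bio20-Bio33) and
two temperature-based potential-evapotranspiration estimates (Bio34-Bio35,
implemented in :mod:`bioclimind.pet`).

Extreme months and quarters are re-identified in every year of the period
(the warmest month of 1963 need not be the warmest month of 1988) and the
statistic of the selected month/window is then averaged across years.
Threshold-based indicators (Bio21, Bio24-Bio26) instead operate on the 12
climatological (mean-over-years) monthly values, with strict inequalities at
the 0 degC and 5 degC thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import temporal_core as tc
from .temporal_core import DailyClimateSeries, MonthlyTable

#: Table of short names and units for every indicator code.
INDICATOR_INFO: dict[int, tuple[str, str]] = {
    1: ("Annual mean temperature", "degC"),
    2: ("Mean diurnal range", "degC"),
    3: ("Isothermality", "%"),
    4: ("Temperature seasonality", "degC"),
    5: ("Max temperature of warmest month", "degC"),
    6: ("Min temperature of coldest month", "degC"),
    7: ("Temperature annual range", "degC"),
    8: ("Mean temperature of wettest quarter", "degC"),
    9: ("Mean temperature of driest quarter", "degC"),
    10: ("Mean temperature of warmest quarter", "degC"),
    11: ("Mean temperature of coldest quarter", "degC"),
    12: ("Annual precipitation", "mm"),
    13: ("Precipitation of wettest month", "mm"),
    14: ("Precipitation of driest month", "mm"),
    15: ("Precipitation seasonality", "%"),
    16: ("Precipitation of wettest quarter", "mm"),
    17: ("Precipitation of driest quarter", "mm"),
    18: ("Precipitation of warmest quarter", "mm"),
    19: ("Precipitation of coldest quarter", "mm"),
    20: ("Ellenberg quotient", "degC/mm"),
    21: ("Yearly positive temperature", "degC"),
    22: ("Sum of annual temperature", "degC"),
    23: ("Ombrothermic index", "mm/degC"),
    24: ("Yearly positive precipitation", "mm"),
    25: ("Modified Kira coldness index", "degC"),
    26: ("Modified Kira warmth index", "degC"),
    27: ("Simplified continentality index", "degC"),
    28: ("Mean temperature of warmest month", "degC"),
    29: ("Mean temperature of coldest month", "degC"),
    30: ("Mean temperature of driest month", "degC"),
    31: ("Mean temperature of wettest month", "degC"),
    32: ("Modified thermicity index", "tenths of degC"),
    33: ("Summer ombrothermic index (May-Aug)", "mm/degC"),
    34: ("Potential evapotranspiration (Hargreaves-Samani)", "mm"),
    35: ("Potential evapotranspiration (Thornthwaite)", "mm"),
}

ALL_CODES = tuple(sorted(INDICATOR_INFO))


@dataclass
class IndicatorField:
    """One 2-D map of one indicator over one climatological period."""

    bio_code: int
    values: np.ndarray
    units: str
    period: tuple[int, int]
    lat: np.ndarray
    lon: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.bio_code not in INDICATOR_INFO:
            raise ValueError(f"unknown indicator code {self.bio_code}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("indicator values must be a 2-D lat/lon map")

    @property
    def long_name(self) -> str:
        return INDICATOR_INFO[self.bio_code][0]


def _mean_over_valid_years(per_year: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Average a (n_years, h, w) stack over the years flagged valid per cell."""
    vals = np.where(valid, per_year, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(vals, axis=0)


def _nanmean_years(per_year: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(per_year, axis=0)


def _guarded_ratio(num, den, scale, invalid):
    """scale * num / den, NaN where *invalid* (never inf)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = scale * num / den
    return np.where(invalid, np.nan, out)


def compute_all(series: DailyClimateSeries, codes=None) -> dict[int, np.ndarray]:
    """Compute the requested indicator maps (default: all 35) in one pass.

    The monthly table, the extreme-month/quarter selections and the
    climatological monthly vectors are shared across indicators, so asking
    for many codes at once costs little more than asking for one.
    Returns ``{code: 2-D array}``.
    """
    codes = sorted(set(ALL_CODES if codes is None else codes))
    bad = [c for c in codes if c not in INDICATOR_INFO]
    if bad:
        raise ValueError(f"unknown indicator code(s) {bad}; valid codes are 1..35")

    table = tc.aggregate_monthly(series)
    out: dict[int, np.ndarray] = {}
    want = set(codes)

    # --- annual statistics -------------------------------------------------
    tg_annual, p_annual = tc.annual_stats(series)
    bio1 = _nanmean_years(tg_annual)
    if 1 in want:
        out[1] = bio1
    if {2, 3} & want:
        out_bio2 = np.mean(series.tx - series.tn, axis=0)
    if 12 in want or 20 in want:
        bio12 = _nanmean_years(p_annual)
        if 12 in want:
            out[12] = bio12

    # --- climatological monthly vectors ------------------------------------
    tg_clim, tg_clim_mean, tg_clim_sd = tc.climatological_monthly_stats(table, "tg", with_sd=True)
    p_clim, p_clim_mean, p_clim_sd = tc.climatological_monthly_stats(table, "p", with_sd=True)
    if 4 in want:
        out[4] = tg_clim_sd
    if 15 in want:
        out[15] = 100.0 * p_clim_sd / (p_clim_mean + 1.0)

    # --- per-year extreme months -------------------------------------------
    # warmest by Tx monthly mean; coldest by Tn; wettest/driest by P total
    need_warm = {5, 7, 3, 20, 27, 28, 32} & want
    need_cold = {6, 7, 3, 27, 29, 32} & want
    need_wet = {13, 31} & want
    need_dry = {14, 30} & want
    if need_warm:
        im, vm = tc.select_extreme_month(table, "tx", "max")
        bio5 = _mean_over_valid_years(tc.month_values_at(table, "tx", im), vm)
        bio28 = _mean_over_valid_years(tc.month_values_at(table, "tg", im), vm)
        if 5 in want:
            out[5] = bio5
        if 28 in want:
            out[28] = bio28
    if need_cold:
        im, vm = tc.select_extreme_month(table, "tn", "min")
        bio6 = _mean_over_valid_years(tc.month_values_at(table, "tn", im), vm)
        bio29 = _mean_over_valid_years(tc.month_values_at(table, "tg", im), vm)
        if 6 in want:
            out[6] = bio6
        if 29 in want:
            out[29] = bio29
    if need_wet:
        im, vm = tc.select_extreme_month(table, "p", "max")
        if 13 in want:
            out[13] = _mean_over_valid_years(tc.month_values_at(table, "p", im), vm)
        if 31 in want:
            out[31] = _mean_over_valid_years(tc.month_values_at(table, "tg", im), vm)
    if need_dry:
        im, vm = tc.select_extreme_month(table, "p", "min")
        if 14 in want:
            out[14] = _mean_over_valid_years(tc.month_values_at(table, "p", im), vm)
        if 30 in want:
            out[30] = _mean_over_valid_years(tc.month_values_at(table, "tg", im), vm)
    # --- derived temperature ranges ----------------------------------------
    if 2 in want:
        out[2] = out_bio2
    if {3, 7} & want:
        bio7 = bio5 - bio6
        if 7 in want:
            out[7] = bio7
        if 3 in want:
            out[3] = _guarded_ratio(out_bio2, bio7, 100.0, bio7 == 0)
    if 27 in want:
        out[27] = bio28 - bio29
    if 32 in want:
        out[32] = 10.0 * (bio1 + bio5 + bio6)

    # --- per-year extreme quarters ------------------------------------------
    if {8, 16} & want:
        _, tg_q, p_q, vq = tc.select_extreme_quarter(table, "p", "max")
        if 8 in want:
            out[8] = _mean_over_valid_years(tg_q, vq)
        if 16 in want:
            out[16] = _mean_over_valid_years(p_q, vq)
    if {9, 17} & want:
        _, tg_q, p_q, vq = tc.select_extreme_quarter(table, "p", "min")
        if 9 in want:
            out[9] = _mean_over_valid_years(tg_q, vq)
        if 17 in want:
            out[17] = _mean_over_valid_years(p_q, vq)
    if {10, 18} & want:
        _, tg_q, p_q, vq = tc.select_extreme_quarter(table, "tg", "max")
        if 10 in want:
            out[10] = _mean_over_valid_years(tg_q, vq)
        if 18 in want:
            out[18] = _mean_over_valid_years(p_q, vq)
    if {11, 19} & want:
        _, tg_q, p_q, vq = tc.select_extreme_quarter(table, "tg", "min")
        if 11 in want:
            out[11] = _mean_over_valid_years(tg_q, vq)
        if 19 in want:
            out[19] = _mean_over_valid_years(p_q, vq)

    # --- climatological threshold sums --------------------------------------
    if {20, 21, 22, 23, 24, 25, 26, 33} & want:
        pos = tg_clim > 0.0  # strict: a month at exactly 0 degC is excluded
        bio21 = np.where(pos, tg_clim, 0.0).sum(axis=0)
        bio21 = np.where(np.isnan(tg_clim).any(axis=0), np.nan, bio21)
        if 21 in want:
            out[21] = bio21
        if 22 in want:
            out[22] = tg_clim.sum(axis=0)
        if 24 in want or 23 in want:
            bio24 = np.where(pos, p_clim, 0.0).sum(axis=0)
            bio24 = np.where(np.isnan(p_clim).any(axis=0) | np.isnan(tg_clim).any(axis=0),
                             np.nan, bio24)
            if 24 in want:
                out[24] = bio24
        tg_clim_nan = np.isnan(tg_clim).any(axis=0)
        if 25 in want:
            bio25 = np.where(tg_clim < 5.0, tg_clim, 0.0).sum(axis=0)
            out[25] = np.where(tg_clim_nan, np.nan, bio25)
        if 26 in want:
            bio26 = np.where(tg_clim > 5.0, tg_clim, 0.0).sum(axis=0)
            out[26] = np.where(tg_clim_nan, np.nan, bio26)
        if 20 in want:
            out[20] = _guarded_ratio(bio28, bio12, 1000.0, (bio12 == 0) | np.isnan(bio12))
        if 23 in want:
            # undefined where no month has positive climatological Tg
            invalid = ~np.isfinite(bio21) | (bio21 <= 0) | ~pos.any(axis=0)
            out[23] = _guarded_ratio(bio24, bio21, 10.0, invalid)
        if 33 in want:
            # late-spring/summer (May-Aug) ombrothermic ratio; Northern-
            # Hemisphere oriented but computed globally
            p_mjja = p_clim[4:8].sum(axis=0)
            t_mjja = tg_clim[4:8].sum(axis=0)
            out[33] = _guarded_ratio(p_mjja, t_mjja, 10.0, ~(t_mjja > 0))

    # --- PET (delegated) -----------------------------------------------------
    if {34, 35} & want:
        from . import pet
        if 34 in want:
            out[34] = pet.pet_hargreaves_map(series, table)
        if 35 in want:
            out[35] = pet.pet_thornthwaite_map(series, table)

    return {c: out[c] for c in codes}


def compute_indicator(code: int, series: DailyClimateSeries) -> IndicatorField:
    """Compute one indicator and wrap it with units and period metadata."""
    if code not in INDICATOR_INFO:
        raise ValueError(f"unknown indicator code {code}; valid codes are 1..35")
    values = compute_all(series, [code])[code]
    name, units = INDICATOR_INFO[code]
    return IndicatorField(
        bio_code=code,
        values=values,
        units=units,
        period=(int(series.years[0]), int(series.years[-1])),
        lat=series.lat,
        lon=series.lon,
        attrs={"long_name": name, "calendar": series.calendar},
    )


def compute_indicator_fields(series: DailyClimateSeries, codes=None) -> list[IndicatorField]:
    """Compute many indicators sharing one monthly-aggregation pass."""
    values = compute_all(series, codes)
    period = (int(series.years[0]), int(series.years[-1]))
    fields = []
    for code, arr in values.items():
        name, units = INDICATOR_INFO[code]
        fields.append(IndicatorField(code, arr, units, period, series.lat, series.lon,
                                     {"long_name": name, "calendar": series.calendar}))
    return fields
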