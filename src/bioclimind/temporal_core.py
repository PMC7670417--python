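"""Calendar-aware temporal aggregation for daily climate series.

Everything the indicator formulas need is built from two steps: collapsing
daily series to per-(year, month) aggregates, and identifying per-year
extreme months and three-month windows ("quarters").  A quarter is any run
of three consecutive calendar months; it belongs to the year of its central
month, so the candidate windows for year *y* include Dec(y-1)-Jan(y)-Feb(y)
and Nov(y)-Dec(y)-Jan(y+1).

Supported calendars: ``standard`` (Gregorian, with leap days), ``noleap``
(fixed 365-day year) and ``360_day`` (twelve 30-day months), matching what
CMIP-class climate models use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

CALENDARS = ("standard", "noleap", "360_day")

# aliases seen in NetCDF "calendar" attributes
_CALENDAR_ALIASES = {
    "standard": "standard",
    "gregorian": "standard",
    "proleptic_gregorian": "standard",
    "noleap": "noleap",
    "365_day": "noleap",
    "360_day": "360_day",
}

_DAYS_NOLEAP = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_DAYS_LEAP = np.array([31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def normalize_calendar(name: str) -> str:
    """Map a NetCDF calendar attribute to one of the supported calendars."""
    try:
        return _CALENDAR_ALIASES[name.lower()]
    except KeyError:
        raise ValueError(
            f"unsupported calendar {name!r}; expected one of {sorted(_CALENDAR_ALIASES)}"
        ) from None


def is_leap_year(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def month_lengths(year: int, calendar: str) -> np.ndarray:
    """Days in each of the 12 months of *year* under *calendar*."""
    calendar = normalize_calendar(calendar)
    if calendar == "360_day":
        return np.full(12, 30)
    if calendar == "noleap":
        return _DAYS_NOLEAP.copy()
    return _DAYS_LEAP.copy() if is_leap_year(year) else _DAYS_NOLEAP.copy()


def days_in_year(year: int, calendar: str) -> int:
    return int(month_lengths(year, calendar).sum())


def time_index(years: np.ndarray, calendar: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-day (year, month, day-of-month) labels for whole years.

    Returns three int arrays of equal length covering Jan 1 of ``years[0]``
    through Dec 31 of ``years[-1]`` under *calendar*.
    """
    ys, ms, ds = [], [], []
    for y in years:
        ml = month_lengths(int(y), calendar)
        for m in range(12):
            n = ml[m]
            ys.append(np.full(n, y))
            ms.append(np.full(n, m + 1))
            ds.append(np.arange(1, n + 1))
    return np.concatenate(ys), np.concatenate(ms), np.concatenate(ds)


@dataclass
class DailyClimateSeries:
    """Daily Tg/Tx/Tn (degC) and precipitation P (mm/day) over whole years.

    Arrays are shaped ``(n_days, n_lat, n_lon)``; missing (ocean) cells are
    NaN throughout.  ``lat``/``lon`` give cell-center coordinates in degrees.
    """

    tg: np.ndarray
    tx: np.ndarray
    tn: np.ndarray
    p: np.ndarray
    years: np.ndarray
    calendar: str
    lat: np.ndarray
    lon: np.ndarray
    day_year: np.ndarray = field(default=None, repr=False)
    day_month: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.calendar = normalize_calendar(self.calendar)
        self.years = np.asarray(self.years, dtype=int)
        for name in ("tg", "tx", "tn", "p"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None, None]
            setattr(self, name, arr)
        self.lat = np.atleast_1d(np.asarray(self.lat, dtype=float))
        self.lon = np.atleast_1d(np.asarray(self.lon, dtype=float))
        if self.day_year is None or self.day_month is None:
            self.day_year, self.day_month, _ = time_index(self.years, self.calendar)
        n_expected = sum(days_in_year(int(y), self.calendar) for y in self.years)
        if self.tg.shape[0] != n_expected:
            raise ValueError(
                f"series has {self.tg.shape[0]} days but {self.years[0]}-{self.years[-1]} "
                f"under the {self.calendar} calendar needs {n_expected} (whole years only)"
            )
        shape = self.tg.shape
        for name in ("tx", "tn", "p"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != tg shape {shape}")
        if shape[1] != self.lat.size or shape[2] != self.lon.size:
            raise ValueError("grid dimensions do not match lat/lon coordinate lengths")

    @property
    def n_years(self) -> int:
        return self.years.size

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.tg.shape[1], self.tg.shape[2]

    def validate(self) -> None:
        """Check physical invariants (Tx >= Tg >= Tn, P >= 0) where finite."""
        with np.errstate(invalid="ignore"):
            if np.any(self.tx < self.tg) or np.any(self.tg < self.tn):
                raise ValueError("temperature ordering violated: require tx >= tg >= tn")
            if np.any(self.p < 0):
                raise ValueError("negative precipitation in series")


@dataclass
class MonthlyTable:
    """Per-(year, month) aggregates, shaped ``(n_years, 12, n_lat, n_lon)``.

    Temperatures are monthly means of the daily values, ``p_total`` is the
    monthly precipitation sum (mm).  Any missing day makes the whole month
    missing.  ``n_days`` is ``(n_years, 12)``.
    """

    tg_mean: np.ndarray
    tx_mean: np.ndarray
    tn_mean: np.ndarray
    p_total: np.ndarray
    n_days: np.ndarray
    years: np.ndarray
    calendar: str
    lat: np.ndarray
    lon: np.ndarray

    @property
    def n_years(self) -> int:
        return self.years.size

    def variable(self, name: str) -> np.ndarray:
        try:
            return {"tg": self.tg_mean, "tx": self.tx_mean,
                    "tn": self.tn_mean, "p": self.p_total}[name]
        except KeyError:
            raise ValueError(f"unknown monthly variable {name!r}") from None


def aggregate_monthly(series: DailyClimateSeries) -> MonthlyTable:
    """Collapse a daily series to the per-(year, month) table.

    Temperatures are averaged, precipitation is summed; a NaN day anywhere in
    a month makes that month's aggregates NaN (plain, non-NaN-skipping
    reductions give exactly this propagation).
    """
    ny = series.n_years
    h, w = series.grid_shape
    n_days = np.stack([month_lengths(int(y), series.calendar) for y in series.years])
    # start offsets of every (year, month) block in the day axis
    starts = np.concatenate([[0], np.cumsum(n_days.ravel())[:-1]])

    def _sum(a):
        return np.add.reduceat(a, starts, axis=0).reshape(ny, 12, h, w)

    counts = n_days.ravel()[:, None, None]
    tg_mean = (_sum(series.tg).reshape(ny * 12, h, w) / counts).reshape(ny, 12, h, w)
    tx_mean = (_sum(series.tx).reshape(ny * 12, h, w) / counts).reshape(ny, 12, h, w)
    tn_mean = (_sum(series.tn).reshape(ny * 12, h, w) / counts).reshape(ny, 12, h, w)
    p_total = _sum(series.p)
    return MonthlyTable(tg_mean, tx_mean, tn_mean, p_total, n_days,
                        series.years, series.calendar, series.lat, series.lon)


def climatological_monthly_stats(
    table: MonthlyTable, variable: str, with_sd: bool = False
):
    """Mean over years of a monthly aggregate, per calendar month.

    Years are weighted equally; years in which a month is missing are simply
    left out of that month's average (a calendar month with no valid year at
    all is NaN).  With ``with_sd=True`` also returns the population standard
    deviation (over 12) of the 12-vector, which is what the temperature- and
    precipitation-seasonality indicators need.
    """
    vals = table.variable(variable)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        clim = np.nanmean(vals, axis=0)  # (12, h, w)
    if not with_sd:
        return clim
    mean12 = clim.mean(axis=0)
    sd12 = np.sqrt(np.mean((clim - mean12) ** 2, axis=0))
    return clim, mean12, sd12


def _arg_extreme(vals: np.ndarray, mode: str, axis: int):
    """First-occurrence argmax/argmin ignoring NaN; all-NaN slices flagged."""
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    bad = np.isnan(vals)
    fill = -np.inf if mode == "max" else np.inf
    filled = np.where(bad, fill, vals)
    idx = filled.argmax(axis=axis) if mode == "max" else filled.argmin(axis=axis)
    valid = ~bad.all(axis=axis)
    return idx, valid


def select_extreme_month(table: MonthlyTable, variable: str, mode: str):
    """Per-year extreme calendar month by one monthly aggregate.

    Returns ``(month_index, valid)`` with shapes ``(n_years, n_lat, n_lon)``:
    the 0-based month achieving the extreme of *variable* (``tg``/``tx``/
    ``tn`` monthly means or ``p`` monthly totals) in each year, ties broken
    toward the earliest calendar month.  ``valid`` is False for years whose
    twelve months are all missing; such years must be excluded downstream.
    """
    vals = table.variable(variable)
    return _arg_extreme(vals, mode, axis=1)


def month_values_at(table: MonthlyTable, variable: str, month_index: np.ndarray) -> np.ndarray:
    """Aggregates of *variable* at a per-year month chosen by another criterion."""
    vals = table.variable(variable)
    return np.take_along_axis(vals, month_index[:, None, :, :], axis=1)[:, 0]


def quarter_stats(table: MonthlyTable):
    """Statistics of every 3-consecutive-month window over the whole period.

    The monthly axis is flattened to length ``n_years * 12``; window *k* is
    centered on flat month *k* and spans months ``k-1 .. k+1``.  Windows that
    would reach before the first or past the last month of the period have no
    complete data and are NaN.  Returns ``(tg_wmean, p_sum)`` of shape
    ``(n_years, 12, n_lat, n_lon)``: the day-weighted mean of daily Tg over
    the window and the 3-month precipitation total.
    """
    ny = table.n_years
    h, w = table.tg_mean.shape[2], table.tg_mean.shape[3]
    n = ny * 12
    tg = table.tg_mean.reshape(n, h, w)
    p = table.p_total.reshape(n, h, w)
    nd = table.n_days.reshape(n).astype(float)[:, None, None]

    tg_days = tg * nd  # degC * day, NaN where month missing
    p_sum = np.full((n, h, w), np.nan)
    tg_wmean = np.full((n, h, w), np.nan)
    if n >= 3:
        p_sum[1:-1] = p[:-2] + p[1:-1] + p[2:]
        num = tg_days[:-2] + tg_days[1:-1] + tg_days[2:]
        den = nd[:-2] + nd[1:-1] + nd[2:]
        tg_wmean[1:-1] = num / den
    return tg_wmean.reshape(ny, 12, h, w), p_sum.reshape(ny, 12, h, w)


def select_extreme_quarter(table: MonthlyTable, variable: str, mode: str):
    """Per-year extreme 3-month window by temperature or precipitation.

    ``variable='p'`` ranks windows by their precipitation total, ``'tg'`` by
    the day-weighted mean of daily Tg.  The twelve candidates of year *y* are
    the windows centered on its calendar months; windows extending past the
    period edges (or containing a missing month) are not candidates.  Ties go
    to the earliest center.  Returns ``(center_index, tg_wmean, p_sum, valid)``
    each ``(n_years, n_lat, n_lon)``; ``tg_wmean``/``p_sum`` describe the
    selected window whatever the criterion was.
    """
    tg_wmean, p_sum = quarter_stats(table)
    if variable == "p":
        crit = p_sum
    elif variable == "tg":
        crit = tg_wmean
    else:
        raise ValueError(f"quarter criterion must be 'tg' or 'p', got {variable!r}")
    idx, valid = _arg_extreme(crit, mode, axis=1)
    sel = idx[:, None, :, :]
    tg_sel = np.take_along_axis(tg_wmean, sel, axis=1)[:, 0]
    p_sel = np.take_along_axis(p_sum, sel, axis=1)[:, 0]
    return idx, tg_sel, p_sel, valid


def annual_stats(series: DailyClimateSeries):
    """Per-year annual mean Tg and annual precipitation total.

    Returns ``(tg_annual_mean, p_annual_total)`` shaped ``(n_years, ...)``.
    """
    lens = np.array([days_in_year(int(y), series.calendar) for y in series.years])
    starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
    tg_sum = np.add.reduceat(series.tg, starts, axis=0)
    p_sum = np.add.reduceat(series.p, starts, axis=0)
    return tg_sum / lens[:, None, None], p_sum
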