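"""NetCDF input/output, unit conversion and the dataset naming scheme.

The published dataset this pipeline reproduces consists of one NetCDF file
per (indicator, data source, scenario, 40-year period); file names follow
``BIO{x}_{SOURCE}[_{RCP}]_{yyyy}_{zz}.nc``, e.g. ``BIO1_HIST_1960_99.nc``
for the reanalysis-driven historical run and ``BIO1_IPSL_45_2060_99.nc`` for
IPSL-CM5A-LR under RCP4.5 over 2060-2099.  With the full coverage (five
ISIMIP-corrected ESMs x two RCPs x two future periods, one extra ESM under
RCP8.5 only, plus the historical run) and 35 indicators this enumerates to
805 files; the 11 future (source, RCP) combinations form the ensemble.

Raw model/reanalysis forcing arrives in Kelvin and kg m-2 s-1; everything
downstream works in degC and mm/day.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .indicators import INDICATOR_INFO, IndicatorField
from .temporal_core import DailyClimateSeries, normalize_calendar, time_index

KELVIN_OFFSET = 273.15
SECONDS_PER_DAY = 86400.0
#: Conventional fill value declared in written files (CMIP practice).
DEFAULT_FILL_VALUE = 1.0e20

#: Default mapping from CF variable names to internal ones.
DEFAULT_VARIABLE_MAP = {"tas": "tg", "tasmax": "tx", "tasmin": "tn", "pr": "p",
                        "tg": "tg", "tx": "tx", "tn": "tn", "p": "p"}

SOURCES = ("HIST", "CMCC", "GFDL", "HADGEM", "IPSL", "MIROC", "NORESM")
FUTURE_PERIODS = ((2040, 2079), (2060, 2099))
HIST_PERIOD = (1960, 1999)

#: Production coverage: source -> tuple of (rcp, period) combinations.
PRODUCTION_COVERAGE: dict[str, tuple] = {
    "HIST": ((None, HIST_PERIOD),),
    "CMCC": tuple(("8.5", p) for p in FUTURE_PERIODS),
    **{
        esm: tuple((rcp, p) for rcp in ("4.5", "8.5") for p in FUTURE_PERIODS)
        for esm in ("GFDL", "HADGEM", "IPSL", "MIROC", "NORESM")
    },
}


# --------------------------------------------------------------------------
# grid description
# --------------------------------------------------------------------------

@dataclass
class GridSpec:
    """A regular lat/lon grid with cell centers offset half a cell from edges."""

    n_lon: int
    n_lat: int
    resolution: float
    lon_start: float = -180.0
    lat_start: float = -90.0

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_start + self.resolution * (np.arange(self.n_lon) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_start + self.resolution * (np.arange(self.n_lat) + 0.5)

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat

    @classmethod
    def global_half_degree(cls) -> "GridSpec":
        """The production 0.5-degree global grid: 720 x 360 = 259200 cells."""
        return cls(n_lon=720, n_lat=360, resolution=0.5)


# --------------------------------------------------------------------------
# unit conversion
# --------------------------------------------------------------------------

def kelvin_to_celsius(values: np.ndarray, force: bool = False) -> np.ndarray:
    """Convert absolute temperatures (K) to degC by subtracting 273.15.

    A guard rejects inputs whose finite mean is below 150, which is only
    plausible if the data are already in degC (double conversion would shift
    everything by another -273.15); pass ``force=True`` to override.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size and not force:
        if finite.mean() < 150.0:
            raise ValueError(
                "temperature values look like degC already (mean < 150); "
                "refusing to subtract 273.15 twice (use force=True to override)"
            )
    return values - KELVIN_OFFSET


def flux_to_mm_per_day(values: np.ndarray) -> np.ndarray:
    """Convert precipitation flux (kg m-2 s-1) to mm/day by multiplying by 86400."""
    values = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(values < 0):
            raise ValueError("negative precipitation flux: corrupt input")
    return values * SECONDS_PER_DAY


# --------------------------------------------------------------------------
# dataset keys and file names
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetKey:
    """Identity of one output file: indicator, source, scenario and period.

    Structural rules (known source, HIST carries no RCP, CMCC exists only
    under RCP8.5) always hold.  With ``strict=True`` (the default) the
    period must additionally be one of the canonical 40-year windows of the
    published dataset; test-scale runs may pass ``strict=False`` to name
    files over arbitrary whole-year periods.
    """

    bio_code: int
    source: str
    rcp: str | None  # "4.5", "8.5" or None for the historical run
    period_start: int
    period_end: int
    strict: bool = field(default=True, compare=False, repr=False)

    def __post_init__(self):
        if self.bio_code not in INDICATOR_INFO:
            raise ValueError(f"invalid indicator code {self.bio_code}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        if self.period_end < self.period_start:
            raise ValueError("period_end before period_start")
        if self.source == "HIST":
            if self.rcp is not None:
                raise ValueError("HIST never carries an RCP segment")
        else:
            if self.rcp not in ("4.5", "8.5"):
                raise ValueError(f"future source {self.source} requires RCP 4.5 or 8.5")
            if self.source == "CMCC" and self.rcp != "8.5":
                raise ValueError("CMCC runs exist only under RCP8.5")
        if self.strict:
            if self.period_end - self.period_start != 39:
                raise ValueError("periods are 40-year windows (end - start must be 39)")
            if self.source == "HIST":
                if (self.period_start, self.period_end) != HIST_PERIOD:
                    raise ValueError("HIST covers the 1960-1999 period")
            elif (self.period_start, self.period_end) not in FUTURE_PERIODS:
                raise ValueError(f"future periods are {FUTURE_PERIODS}")


def encode_filename(key: DatasetKey) -> str:
    """File name for a dataset key, e.g. ``BIO1_CMCC_85_2060_99.nc``."""
    parts = [f"BIO{key.bio_code}", key.source]
    if key.rcp is not None:
        parts.append(key.rcp.replace(".", ""))
    parts += [str(key.period_start), f"{key.period_end % 100:02d}"]
    return "_".join(parts) + ".nc"


_NAME_RE = re.compile(
    r"^BIO(?P<code>\d{1,2})_(?P<source>[A-Z]+)(?:_(?P<rcp>45|85))?"
    r"_(?P<start>\d{4})_(?P<end>\d{2})\.nc$"
)


def decode_filename(name: str) -> DatasetKey:
    """Parse a dataset file name back into its :class:`DatasetKey`."""
    m = _NAME_RE.match(name)
    if not m:
        # point at the first segment that breaks the pattern
        parts = name.split("_")
        pos = 0 if not parts[0].startswith("BIO") else 1
        raise ValueError(
            f"file name {name!r} does not match 'BIO<x>_<SOURCE>[_<rcp>]_<yyyy>_<zz>.nc' "
            f"(mismatch around segment {pos})"
        )
    code = int(m["code"])
    start = int(m["start"])
    end = start - (start % 100) + int(m["end"])
    if end < start:
        end += 100
    rcp = {"45": "4.5", "85": "8.5", None: None}[m["rcp"]]
    return DatasetKey(code, m["source"], rcp, start, end, strict=False)


def enumerate_dataset(coverage: dict | None = None, n_indicators: int = 35) -> list[DatasetKey]:
    """Every DatasetKey implied by a coverage matrix.

    ``coverage`` maps source name to (rcp, (start, end)) combinations;
    defaults to the production coverage, which yields 23 runs and hence
    ``35 * 23 = 805`` keys.
    """
    coverage = PRODUCTION_COVERAGE if coverage is None else coverage
    keys = []
    for code in range(1, n_indicators + 1):
        for source, cells in coverage.items():
            for rcp, (start, end) in cells:
                keys.append(DatasetKey(code, source, rcp, start, end))
    return keys


def ensemble_members(coverage: dict | None = None) -> list[tuple[str, str]]:
    """The future (source, rcp) combinations — 11 under production coverage."""
    coverage = PRODUCTION_COVERAGE if coverage is None else coverage
    members = []
    for source, cells in coverage.items():
        if source == "HIST":
            continue
        for rcp in sorted({rcp for rcp, _ in cells}):
            members.append((source, rcp))
    return members


# --------------------------------------------------------------------------
# NetCDF read/write
# --------------------------------------------------------------------------

def _orient_latitude(ds: xr.Dataset) -> xr.Dataset:
    if ds["lat"].values.size > 1 and ds["lat"].values[0] > ds["lat"].values[-1]:
        ds = ds.isel(lat=slice(None, None, -1))
    return ds


def read_daily_series(
    paths: dict[str, str],
    period: tuple[int, int],
    variable_map: dict[str, str] | None = None,
    convert_units: bool = True,
) -> DailyClimateSeries:
    """Read daily forcing NetCDFs into one converted series.

    ``paths`` maps file variable names (e.g. ``tas``/``tasmax``/``tasmin``/
    ``pr``) to file paths; one file may hold several variables, in which case
    the same path can be repeated.  The period (start year, end year) is
    subset out of each file; the calendar is taken from the time coordinate.
    Temperatures are converted K -> degC and precipitation flux -> mm/day
    unless ``convert_units=False`` (for files already in indicator units).
    """
    variable_map = dict(DEFAULT_VARIABLE_MAP, **(variable_map or {}))
    start, end = period
    arrays: dict[str, np.ndarray] = {}
    lat = lon = None
    calendar = None
    for var, path in paths.items():
        if var not in variable_map:
            raise ValueError(f"unknown input variable {var!r}; add it to the variable map")
        internal = variable_map[var]
        with xr.open_dataset(path, decode_times=xr.coders.CFDatetimeCoder(use_cftime=True)) as ds:
            ds = _orient_latitude(ds)
            da = ds[var]
            times = da["time"].values
            cal = normalize_calendar(getattr(times[0], "calendar", "standard"))
            years = np.array([t.year for t in times])
            if start < years.min() or end > years.max():
                raise ValueError(
                    f"requested period {start}-{end} outside data span "
                    f"{years.min()}-{years.max()} in {path}"
                )
            sel = (years >= start) & (years <= end)
            da = da.isel(time=np.nonzero(sel)[0]).transpose("time", "lat", "lon")
            if lat is None:
                lat, lon = da["lat"].values, da["lon"].values
                calendar = cal
            else:
                if da["lat"].size != lat.size or da["lon"].size != lon.size \
                        or not (np.allclose(da["lat"].values, lat) and np.allclose(da["lon"].values, lon)):
                    raise ValueError(f"grid mismatch between input variables (at {var!r})")
                if cal != calendar:
                    raise ValueError("calendar mismatch between input variables")
            vals = da.values.astype(float)
        if convert_units:
            vals = flux_to_mm_per_day(vals) if internal == "p" else kelvin_to_celsius(vals)
        arrays[internal] = vals
    missing = {"tg", "tx", "tn", "p"} - set(arrays)
    if missing:
        raise ValueError(f"missing input variables for {sorted(missing)}")
    return DailyClimateSeries(
        tg=arrays["tg"], tx=arrays["tx"], tn=arrays["tn"], p=arrays["p"],
        years=np.arange(start, end + 1), calendar=calendar, lat=lat, lon=lon,
    )


def write_daily_series(series: DailyClimateSeries, path, raw_units: bool = False) -> None:
    """Write a daily series to one NetCDF file.

    With ``raw_units=True`` the variables are emitted as CF ``tas``/
    ``tasmax``/``tasmin`` (K) and ``pr`` (kg m-2 s-1), emulating the forcing
    files the pipeline normally starts from.
    """
    import cftime

    day_y, day_m, day_d = time_index(series.years, series.calendar)
    cal = {"standard": "standard", "noleap": "noleap", "360_day": "360_day"}[series.calendar]
    times = [cftime.datetime(y, m, d, calendar=cal) for y, m, d in zip(day_y, day_m, day_d)]
    if raw_units:
        data = {
            "tas": (series.tg + KELVIN_OFFSET, "K"),
            "tasmax": (series.tx + KELVIN_OFFSET, "K"),
            "tasmin": (series.tn + KELVIN_OFFSET, "K"),
            "pr": (series.p / SECONDS_PER_DAY, "kg m-2 s-1"),
        }
    else:
        data = {
            "tg": (series.tg, "degC"), "tx": (series.tx, "degC"),
            "tn": (series.tn, "degC"), "p": (series.p, "mm/day"),
        }
    ds = xr.Dataset(
        {name: (("time", "lat", "lon"), vals, {"units": units})
         for name, (vals, units) in data.items()},
        coords={"time": times, "lat": series.lat, "lon": series.lon},
    )
    ds.to_netcdf(path)


def write_indicator_field(field: IndicatorField, key: DatasetKey, out_dir,
                          fill_value: float = DEFAULT_FILL_VALUE) -> str:
    """Write one indicator map as a NetCDF file named per the dataset scheme."""
    from pathlib import Path

    name = encode_filename(key)
    path = Path(out_dir) / name
    var = f"BIO{field.bio_code}"
    attrs = {"units": field.units, "long_name": field.long_name}
    attrs.update({k: v for k, v in field.attrs.items() if isinstance(v, (str, int, float))})
    ds = xr.Dataset(
        {var: (("lat", "lon"), field.values, attrs)},
        coords={"lat": field.lat, "lon": field.lon},
        attrs={
            "period_start": field.period[0], "period_end": field.period[1],
            "source": key.source, "rcp": key.rcp or "none",
        },
    )
    ds[var].encoding["_FillValue"] = fill_value
    ds.to_netcdf(path)
    return str(path)


def read_indicator_field(path) -> tuple[IndicatorField, DatasetKey]:
    """Read back an indicator file written by :func:`write_indicator_field`."""
    from pathlib import Path

    path = Path(path)
    key = decode_filename(path.name)
    with xr.open_dataset(path) as ds:
        ds = _orient_latitude(ds)
        var = f"BIO{key.bio_code}"
        if var not in ds:
            raise ValueError(f"{path.name}: expected variable {var!r}, found {list(ds.data_vars)}")
        da = ds[var]
        fld = IndicatorField(
            bio_code=key.bio_code,
            values=da.values.astype(float),
            units=da.attrs.get("units", INDICATOR_INFO[key.bio_code][1]),
            period=(int(ds.attrs.get("period_start", key.period_start)),
                    int(ds.attrs.get("period_end", key.period_end))),
            lat=ds["lat"].values, lon=ds["lon"].values,
            attrs=dict(da.attrs),
        )
    return fld, key
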