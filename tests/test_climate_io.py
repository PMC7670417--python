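"""Unit conversion, file naming scheme and NetCDF round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bioclimind import climate_io as cio
from bioclimind import (
    DatasetKey,
    GridSpec,
    compute_indicator,
    constant_config,
    generate_daily_climate,
)


class TestUnitConversion:
    def test_kelvin_to_celsius(self):
        assert cio.kelvin_to_celsius(np.array([273.15, 283.15])) == pytest.approx([0.0, 10.0])

    def test_missing_values_propagate(self):
        out = cio.kelvin_to_celsius(np.array([273.15, np.nan]))
        assert np.isnan(out[1]) and out[0] == 0.0

    def test_double_conversion_guard(self):
        with pytest.raises(ValueError, match="degC already"):
            cio.kelvin_to_celsius(np.array([10.0, 20.0]))
        # force overrides the guard
        assert cio.kelvin_to_celsius(np.array([10.0]), force=True)[0] == pytest.approx(-263.15)

    def test_flux_to_mm_per_day(self):
        assert cio.flux_to_mm_per_day(np.array([1.0]))[0] == 86400.0
        assert cio.flux_to_mm_per_day(np.array([0.0]))[0] == 0.0
        assert cio.flux_to_mm_per_day(np.array([1.0 / 86400.0]))[0] == pytest.approx(1.0)

    def test_negative_flux_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            cio.flux_to_mm_per_day(np.array([-1e-6]))


class TestNamingScheme:
    @pytest.mark.parametrize("key,name", [
        (DatasetKey(1, "HIST", None, 1960, 1999), "BIO1_HIST_1960_99.nc"),
        (DatasetKey(1, "CMCC", "8.5", 2060, 2099), "BIO1_CMCC_85_2060_99.nc"),
        (DatasetKey(1, "GFDL", "8.5", 2060, 2099), "BIO1_GFDL_85_2060_99.nc"),
        (DatasetKey(1, "IPSL", "4.5", 2060, 2099), "BIO1_IPSL_45_2060_99.nc"),
        (DatasetKey(35, "NORESM", "4.5", 2040, 2079), "BIO35_NORESM_45_2040_79.nc"),
    ])
    def test_encode_examples(self, key, name):
        assert cio.encode_filename(key) == name
        assert cio.decode_filename(name) == key

    def test_roundtrip_over_full_dataset(self):
        keys = cio.enumerate_dataset()
        assert len(keys) == len(set(keys)) == 805
        for key in keys:
            assert cio.decode_filename(cio.encode_filename(key)) == key

    def test_future_members_number_eleven(self):
        assert len(cio.ensemble_members()) == 11

    def test_single_indicator_hist_only(self):
        keys = cio.enumerate_dataset(coverage={"HIST": ((None, (1960, 1999)),)}, n_indicators=1)
        assert keys == [DatasetKey(1, "HIST", None, 1960, 1999)]

    @pytest.mark.parametrize("bad", [
        "BIO99_GFDL_85_2060_99.nc",   # invalid code
        "BIO1_FOO_85_2060_99.nc",     # unknown source
        "BIO1_CMCC_45_2060_99.nc",    # CMCC has no RCP4.5 runs
        "BIO1_GFDL_2060_99.nc",       # future run missing RCP
        "BIO1_HIST_85_1960_99.nc",    # HIST never carries an RCP
        "completely-wrong.nc",
    ])
    def test_malformed_or_invalid_names_rejected(self, bad):
        with pytest.raises(ValueError):
            cio.decode_filename(bad)

    @given(code=st.integers(1, 35),
           source=st.sampled_from(("GFDL", "HADGEM", "IPSL", "MIROC", "NORESM")),
           rcp=st.sampled_from(("4.5", "8.5")),
           period=st.sampled_from(((2040, 2079), (2060, 2099))))
    @settings(derandomize=True, max_examples=60)
    def test_roundtrip_property(self, code, source, rcp, period):
        key = DatasetKey(code, source, rcp, *period)
        assert cio.decode_filename(cio.encode_filename(key)) == key


def test_global_grid_bookkeeping():
    grid = GridSpec.global_half_degree()
    assert (grid.n_lon, grid.n_lat, grid.n_cells) == (720, 360, 259200)
    assert grid.lon_centers[0] == -179.75 and grid.lon_centers[-1] == 179.75
    assert grid.lat_centers[0] == -89.75 and grid.lat_centers[-1] == 89.75
    assert np.allclose(np.diff(grid.lat_centers), 0.5)


class TestNetCDFRoundTrips:
    @pytest.mark.parametrize("calendar", ["standard", "noleap", "360_day"])
    def test_daily_series_roundtrip_raw_units(self, tmp_path, calendar):
        """Write raw-unit forcing, read it back through the converting reader."""
        s = generate_daily_climate(constant_config(calendar=calendar))
        path = tmp_path / "forcing.nc"
        cio.write_daily_series(s, path, raw_units=True)
        paths = {v: str(path) for v in ("tas", "tasmax", "tasmin", "pr")}
        back = cio.read_daily_series(paths, (2000, 2004))
        assert back.calendar == calendar
        assert np.allclose(back.tg, s.tg) and np.allclose(back.p, s.p)

    def test_period_subsetting(self, tmp_path):
        s = generate_daily_climate(constant_config(years=range(1998, 2006)))
        path = tmp_path / "forcing.nc"
        cio.write_daily_series(s, path, raw_units=True)
        paths = {v: str(path) for v in ("tas", "tasmax", "tasmin", "pr")}
        sub = cio.read_daily_series(paths, (2000, 2003))
        assert list(sub.years) == [2000, 2001, 2002, 2003]
        assert sub.tg.shape[0] == 4 * 360

    def test_period_outside_span_rejected(self, tmp_path):
        s = generate_daily_climate(constant_config())
        path = tmp_path / "forcing.nc"
        cio.write_daily_series(s, path, raw_units=True)
        paths = {v: str(path) for v in ("tas", "tasmax", "tasmin", "pr")}
        with pytest.raises(ValueError, match="outside data span"):
            cio.read_daily_series(paths, (1960, 1999))

    def test_grid_mismatch_between_variables_rejected(self, tmp_path):
        s1 = generate_daily_climate(constant_config(lat=(45.0,)))
        s2 = generate_daily_climate(constant_config(lat=(44.0,)))
        p1, p2 = tmp_path / "a.nc", tmp_path / "b.nc"
        cio.write_daily_series(s1, p1, raw_units=True)
        cio.write_daily_series(s2, p2, raw_units=True)
        paths = {"tas": str(p1), "tasmax": str(p2), "tasmin": str(p1), "pr": str(p1)}
        with pytest.raises(ValueError, match="grid mismatch"):
            cio.read_daily_series(paths, (2000, 2004))

    def test_indicator_field_roundtrip(self, tmp_path, constant_series):
        fld = compute_indicator(1, constant_series)
        fld.values[0, 0] = np.nan  # a missing cell must survive the trip
        key = DatasetKey(1, "HIST", None, 1960, 1999)
        path = cio.write_indicator_field(fld, key, tmp_path)
        assert path.endswith("BIO1_HIST_1960_99.nc")
        back, back_key = cio.read_indicator_field(path)
        assert back_key == key
        assert back.units == fld.units
        assert np.isnan(back.values[0, 0])
        finite = np.isfinite(fld.values)
        assert np.array_equal(back.values[finite], fld.values[finite])

    def test_descending_latitude_flipped_on_read(self, tmp_path):
        import xarray as xr

        vals = np.arange(6, dtype=float).reshape(3, 2)
        ds = xr.Dataset({"BIO1": (("lat", "lon"), vals, {"units": "degC"})},
                        coords={"lat": [60.0, 0.0, -60.0], "lon": [0.0, 90.0]})
        path = tmp_path / "BIO1_HIST_1960_99.nc"
        ds.to_netcdf(path)
        fld, _ = cio.read_indicator_field(path)
        assert fld.lat[0] < fld.lat[-1]
        assert np.array_equal(fld.values, vals[::-1])
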