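"""Indicator formulas: analytic cases, algebraic identities, oracle parity."""

import math

import numpy as np
import pytest

from bioclimind import (
    SyntheticClimateConfig,
    compute_all,
    compute_indicator,
    constant_config,
    generate_daily_climate,
)

from conftest import cell_to_daily_dicts, random_cell_series
import reference_impl as ref

CONSTANT_EXPECTED = {
    1: 10.0, 2: 10.0, 3: 100.0, 4: 0.0, 5: 15.0, 6: 5.0, 7: 10.0,
    8: 10.0, 9: 10.0, 10: 10.0, 11: 10.0, 12: 720.0, 13: 60.0, 14: 60.0,
    15: 0.0, 16: 180.0, 17: 180.0, 18: 180.0, 19: 180.0,
    20: 1000.0 * 10.0 / 720.0, 21: 120.0, 22: 120.0, 23: 60.0, 24: 720.0,
    25: 0.0, 26: 120.0, 27: 0.0, 28: 10.0, 29: 10.0, 30: 10.0, 31: 10.0,
    32: 300.0, 33: 60.0,
}


@pytest.fixture(scope="module")
def constant_values(constant_series):
    return compute_all(constant_series, range(1, 34))


@pytest.mark.parametrize("code", sorted(CONSTANT_EXPECTED))
def test_constant_climate_closed_forms(constant_values, code):
    """tg=10, tx=15, tn=5, p=2 on a 360-day calendar pins every non-PET
    indicator to a closed-form value."""
    assert constant_values[code][0, 0] == pytest.approx(CONSTANT_EXPECTED[code], abs=1e-9)


def test_sinusoidal_zero_mean_temperature_averages_out():
    """A pure annual cycle with zero mean leaves Bio1 at exactly zero."""
    cfg = SyntheticClimateConfig(
        lat=np.array([45.0]), lon=np.array([0.0]), years=range(2000, 2004),
        calendar="noleap", tg_mean=0.0, tg_amplitude=12.0, diurnal_range=6.0,
        precip_annual=365.0, precip_seasonality=0.0,
        temp_noise_sd=0.0, precip_stochastic=False, seed=1)
    out = compute_all(generate_daily_climate(cfg), [1])
    assert out[1][0, 0] == pytest.approx(0.0, abs=1e-10)


def test_precip_seasonality_noleap_constant_rate():
    """Constant 2 mm/day on a no-leap calendar: the 12 monthly totals vary
    only through month lengths; Bio15 follows from their direct CV."""
    s = generate_daily_climate(constant_config(calendar="noleap"))
    totals = np.array([62, 56, 62, 60, 62, 60, 62, 62, 60, 62, 60, 62], dtype=float)
    sd = totals.std()  # population SD over the 12 months
    expected = 100.0 * sd / (totals.mean() + 1.0)
    out = compute_all(s, [15])
    assert out[15][0, 0] == pytest.approx(expected, rel=1e-12)


def test_annual_precip_totals_by_calendar():
    assert compute_all(generate_daily_climate(constant_config(calendar="noleap")),
                       [12])[12][0, 0] == pytest.approx(730.0)
    assert compute_all(generate_daily_climate(constant_config(calendar="360_day")),
                       [12])[12][0, 0] == pytest.approx(720.0)


def test_negative_constant_temperature_threshold_sums():
    """At tg=-10 all threshold sums flip: no positive months, Kira coldness
    keeps its negative sign."""
    s = generate_daily_climate(constant_config(tg=-10.0, tx=-5.0, tn=-15.0))
    out = compute_all(s, [21, 22, 23, 24, 25, 26])
    assert out[21][0, 0] == 0.0
    assert out[22][0, 0] == pytest.approx(-120.0)
    assert out[24][0, 0] == 0.0
    assert out[25][0, 0] == pytest.approx(-120.0)
    assert out[26][0, 0] == 0.0
    assert np.isnan(out[23][0, 0])  # no month with positive Tg climatology


def test_guarded_divisions_yield_missing_not_inf():
    # tx == tn -> Bio7 = 0 -> Bio3 undefined; p = 0 -> Bio12 = 0 -> Bio20 undefined
    s = generate_daily_climate(constant_config(tg=10.0, tx=10.0, tn=10.0, p=0.0))
    out = compute_all(s, [3, 7, 12, 20])
    assert out[7][0, 0] == 0.0
    assert np.isnan(out[3][0, 0])
    assert out[12][0, 0] == 0.0
    assert np.isnan(out[20][0, 0])
    assert np.all(np.isfinite(out[3][np.isfinite(out[3])]))


def test_all_missing_cell_propagates(constant_series):
    s = constant_series
    import copy

    s2 = copy.deepcopy(s)
    s2.tg[:, 0, 0] = np.nan
    s2.tx[:, 0, 0] = np.nan
    s2.tn[:, 0, 0] = np.nan
    s2.p[:, 0, 0] = np.nan
    out = compute_all(s2)
    for code, arr in out.items():
        assert np.isnan(arr[0, 0]), f"Bio{code} not missing on an all-missing cell"


def test_dispatch_identity_and_errors(constant_series):
    fld = compute_indicator(1, constant_series)
    assert fld.bio_code == 1 and fld.units == "degC"
    assert fld.values[0, 0] == pytest.approx(10.0)
    assert fld.period == (2000, 2004)
    for bad in (0, 36):
        with pytest.raises(ValueError, match="unknown indicator code"):
            compute_indicator(bad, constant_series)


def test_algebraic_invariants_on_stochastic_grid(noisy_series):
    """Order constraints and identities hold on every cell of a noisy grid."""
    out = compute_all(noisy_series, range(1, 34))
    b = {c: out[c] for c in out}
    tol = 1e-9
    assert np.all(b[5] >= b[28] - tol) and np.all(b[28] >= b[29] - tol) \
        and np.all(b[29] >= b[6] - tol)
    assert np.all(b[10] >= b[1] - tol) and np.all(b[1] >= b[11] - tol)
    assert np.all(b[13] >= b[14] - tol)
    assert np.all(b[16] >= b[17] - tol)
    assert np.all(b[12] >= b[16] - tol) and np.all(b[16] >= b[13] - tol)
    assert np.all(b[21] >= b[22] - tol)
    assert np.all(b[7] >= b[27] - tol) and np.all(b[27] >= -tol)
    np.testing.assert_allclose(b[7], b[5] - b[6], atol=1e-9)
    np.testing.assert_allclose(b[27], b[28] - b[29], atol=1e-9)
    np.testing.assert_allclose(b[32], 10.0 * (b[1] + b[5] + b[6]), atol=1e-8)
    np.testing.assert_allclose(b[3], 100.0 * b[2] / b[7], atol=1e-9)
    # Kira partition: coldness + warmth = total off the 5 degC boundary
    np.testing.assert_allclose(b[25] + b[26], b[22], atol=1e-8)


def test_bio22_tracks_twelve_times_bio1():
    """The 12-month temperature sum approximates 12 x the annual mean.

    The residual is pure month-length arithmetic: on a no-leap calendar the
    unweighted 12-month sum of a sinusoid with half-amplitude A differs from
    12 x the day-weighted mean by about 0.055*A, so the 0.5 degC bound holds
    on smooth cells with moderate seasonality; with equal 30-day months and
    month-constant temperature the identity is exact.
    """
    cfg = SyntheticClimateConfig(
        lat=np.array([-60.0, -30.0, 0.0, 30.0, 60.0]), lon=np.array([0.0]),
        years=range(2000, 2005), calendar="noleap",
        tg_amplitude=8.0, temp_noise_sd=0.0, precip_stochastic=False, seed=3)
    out = compute_all(generate_daily_climate(cfg), [1, 22])
    assert np.all(np.abs(out[22] - 12.0 * out[1]) <= 0.5)
    s360 = generate_daily_climate(constant_config())
    out360 = compute_all(s360, [1, 22])
    np.testing.assert_allclose(out360[22], 12.0 * out360[1], atol=1e-10)


def test_engine_matches_reference_implementation_exactly():
    """Full-engine oracle parity on random single cells, all three calendars."""
    rng = np.random.default_rng(99)
    n_checked = 0
    for trial in range(18):
        cal = ("standard", "noleap", "360_day")[trial % 3]
        s = random_cell_series(rng, cal, n_years=4)
        engine = compute_all(s)
        expect = ref.reference_indicators(
            cell_to_daily_dicts(s), list(s.years), cal, float(s.lat[0]))
        for code in range(1, 36):
            e, r = float(engine[code][0, 0]), expect[code]
            if math.isnan(r):
                assert math.isnan(e), f"Bio{code}: engine {e}, oracle NaN"
            else:
                assert e == pytest.approx(r, rel=1e-9, abs=1e-9), \
                    f"Bio{code} mismatch on {cal} cell (engine {e}, oracle {r})"
        n_checked += 1
    assert n_checked == 18
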