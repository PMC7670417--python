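# Methods

## Scope and model

`bioclimind` computes 35 bioclimatic indicators — long-term scalar summaries
of daily mean/maximum/minimum temperature (Tg, Tx, Tn, °C) and precipitation
(P, mm/day) used as environmental predictors in species distribution
modelling and related ecological work — over a multi-year "climatological"
period on a regular lat/lon grid, and combines indicator maps from several
climate-model runs into ensemble anomaly and spread maps.

The defining feature of the indicator family is *per-year* identification of
extremes: the warmest/coldest/wettest/driest month or quarter is found
separately in every year of the period, the statistic of the selected
month/window is taken, and only then is the average across years formed.
This respects inter-annual variability of the seasonal cycle (the wettest
month of one year need not be the wettest month of another).

### Temporal machinery

* **Monthly table.** Daily series are collapsed to per-(year, month)
  aggregates: temperature means, precipitation totals. Any missing (NaN) day
  makes the whole month missing. Three calendars are supported — standard
  Gregorian, no-leap (365-day) and 360-day — read from the NetCDF time
  coordinate; all month/quarter logic is calendar-generic.
* **Quarters** are *overlapping* windows of three consecutive calendar
  months, attributed to the year of the central month. Year *y* therefore
  has twelve candidate windows, including Dec(y−1)–Jan(y)–Feb(y) and
  Nov(y)–Dec(y)–Jan(y+1). Windows that would need a month outside the period
  (or a missing month) are not candidates; a year with no complete candidate
  is excluded from quarter-based indicators only.
* **Window statistics.** Precipitation criterion/statistic: sum of the three
  monthly totals. Temperature: the day-weighted mean of daily Tg over the
  window (monthly means weighted by month length), which equals the plain
  mean over the window's days.
* **Tie-breaking.** Earliest calendar month / earliest window center wins.
  Any deterministic rule would do scientifically; one is mandatory for
  reproducibility, and "earliest" is the simplest to state and verify.
* **Climatological monthly values** (used by Bio4, Bio15, Bio21–Bio26,
  Bio33) are unweighted means across years of the monthly aggregates; years
  missing a month drop out of that month's average.

### Indicator conventions

Formulas follow the WorldClim/ANUCLIM lineage for Bio1–Bio19 plus
Rivas-Martínez (Bio21–24, 32, 33), Kira (Bio25, 26), Ellenberg (Bio20) and a
Driscoll-type continentality index (Bio27). Conventions that are genuinely
open and the choices made here:

* **Bio4** is the standard deviation of the 12 climatological monthly Tg
  means in °C, with *no* ×100 scaling.
* **Bio4/Bio15 SD form**: population (divide by 12) — the 12 calendar months
  are the whole population of months, not a sample.
* **Bio15** uses climatological monthly precipitation *totals* (mm/month),
  consistent with Bio13/14; the denominator is mean+1 to protect fully arid
  cells.
* **Bio21/24/25/26 thresholds** are strict inequalities; a month whose
  climatology sits exactly at 0 °C or 5 °C is excluded from both sides.
  Bio25 keeps its (possibly negative) sign.
* **Bio32** = 10·(Bio1 + Bio5 + Bio6): the ×10 realizes the thermicity
  index's "tenths of °C" unit.
* **Bio33** = 10 × (ΣP May–Aug)/(ΣTg May–Aug), mirroring the Bio23
  construction; computed globally although the May–August window is
  Northern-Hemisphere oriented — masking the Southern Hemisphere is left to
  the user.
* **Guarded divisions** (Bio3, Bio20, Bio23, Bio33) return missing values,
  never infinities: Bio3 where the annual range is 0, Bio20 where annual
  precipitation is 0, Bio23/33 where the temperature sum is non-positive.

A useful identity caveat: Bio22 ≈ 12·Bio1 only up to month-length
weighting. On a no-leap calendar the unweighted 12-month sum of a sinusoidal
cycle with half-amplitude *A* differs from 12× the day-weighted annual mean
by ≈0.055·A °C, so the approximation is tight only for moderate seasonality
and exact on 360-day calendars with month-constant temperature.

### Potential evapotranspiration

* **Bio34, Hargreaves–Samani (1985)**: monthly PET/day =
  0.0023·Ra·(Tg+17.8)·√TD, with TD the monthly mean diurnal range and Ra the
  FAO-56 extraterrestrial radiation (solar constant 0.082 MJ m⁻² min⁻¹,
  ×0.408 to evaporation-equivalent mm/day) at the month's midpoint
  day-of-year. The (Tg+17.8) factor is clamped at 0.
* **Bio35, Thornthwaite (1948)**: 16·(10·Tm/I)^a·(N/12)·(days/30) for months
  with Tm>0; the heat index I = Σ(Tm/5)^1.514 is computed *per year* and the
  annual PET sums averaged, mirroring the per-year-then-average pattern of
  all other indicators. No hot-month (>26.5 °C) variant is applied.
* Solar geometry is evaluated at the cumulative mid-month day-of-year under
  the series' own calendar (360-day years use a 360-day orbital phase), with
  day length clamped to [0, 24] poleward of the polar circles.
* Missing policy: a missing month invalidates its year; a cell's PET is the
  mean over valid years provided ≥80% of years are valid, else missing.

### Ensemble statistics

Anomaly = cellwise ensemble mean minus the historical reference (percent
mode divides by |reference| ×100). RSD = 100·s/|mean| with the *sample*
(n−1) standard deviation — appropriate for the small (n = 11) production
ensemble. Percent quantities are unstable near zero denominators (desert
cells for precipitation indicators), so both are masked where the
denominator magnitude falls below ε, configurable and defaulting to 10⁻⁶ of
the field's largest finite magnitude; the ε used is recorded in the output
metadata.

### I/O conventions

Inputs are CF-style NetCDF daily series (`tas`/`tasmax`/`tasmin` in K,
`pr` in kg m⁻² s⁻¹; a variable-name map accepts other spellings), converted
on read by −273.15 and ×86400. A guard refuses to "convert" temperatures
whose mean is below 150, which would indicate data already in °C. Files with
descending latitude are flipped to the single internal orientation
(ascending). Missing cells are NaN internally; written files declare a
1 × 10²⁰ fill value (the common CMIP convention — the published files'
sentinel is not documented, so the writer's own is declared in metadata).
Output names follow `BIO{x}_{SOURCE}[_{RCP}]_{yyyy}_{zz}.nc`; the canonical
coverage (one historical run, five ESMs × two RCPs × two 40-year future
periods, one ESM under RCP8.5 only) enumerates to 805 files and 11 ensemble
members. Keys for non-canonical (e.g. test-scale) periods are permitted in
lenient mode; strict mode pins the three production periods.

## Synthetic data

The generator emulates the gross structure of gridded daily forcing:

* Tg = tg_mean(lat) + A(lat)·cos(2π(d − d_peak)/L), peak at mid-July,
  shifted half a year south of the equator. Because the cosine is sampled
  uniformly over whole years, its annual mean vanishes exactly — the
  noiseless Bio1 recovers tg_mean(lat) to rounding.
* Tx/Tn = Tg ± half the diurnal range (so Tx ≥ Tg ≥ Tn by construction).
* Daily precipitation = seasonal mean intensity (annual total =
  precip_annual(lat)) optionally multiplied by unit-mean exponential noise —
  non-negative by construction, with distinct wettest/driest months.
* Defaults describe a plausible pole-to-pole transect: equatorial mean 27 °C
  falling quadratically to −15 °C at the poles; seasonal half-amplitude 2 °C
  (tropics) to 20 °C (poles); 8 °C diurnal range; annual precipitation
  2000 mm (wet tropics) to 200 mm (poles) with 0.5 seasonality; 1 °C daily
  temperature noise. One integer seed controls all randomness.

Deliberately *not* emulated: spatial correlation, weather persistence
(autocorrelation), extreme-value statistics, drizzle/dry-day structure, or
any specific model's bias structure. Passing tests therefore demonstrate the
correctness of the aggregation and formula machinery, not skill on real
forcing; real-data quirks (e.g. inhomogeneities, sub-monthly extremes) never
reach the indicator definitions, which operate only on monthly aggregates.

## Problem sizes

Tests and the acceptance script run on small grids (single cells to 6×8) and
short periods (3–6 years) — the machinery is size-agnostic and the formulas
are exercised identically at any scale; the production configuration
(720×360, 40 years) differs only in array extent. All evaluation is eager
NumPy; the pipeline processes one variable set in memory at a time.

## Verification strategy

Every formula is cross-checked against an independent, deliberately naive
straight-loop reference implementation (explicit Python loops per day, month
and year; its own FAO-56 transcription for solar geometry) on randomized
single-cell series under all three calendars, demanding exact agreement
including tie-breaks. Closed-form cases (constant climate on a 360-day
calendar) pin every non-PET indicator analytically. Algebraic identities
(Bio7 = Bio5−Bio6, Bio32 = 10·(Bio1+Bio5+Bio6), Kira partition
Bio25+Bio26 = Bio22, order constraints) are asserted on every cell of
stochastic grids.

## Known limitations

* No regridding: all input variables must share one grid.
* No bias correction: inputs are assumed already corrected.
* Thornthwaite/Hargreaves constants are the canonical published ones; the
  choice of per-year (vs climatological) heat index and the FAO-56 Ra
  tabulation are this package's documented decisions.
* Bio33 is reported globally despite its Northern-Hemisphere orientation.
* Ensemble combination is equal-weight only; no model skill weighting.
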