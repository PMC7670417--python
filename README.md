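# bioclimind

Bioclimatic indicators (BIO1–BIO35) from daily gridded climate series, with
multi-model ensemble anomaly and spread maps.

Ecologists and biogeographers rarely feed raw meteorology into species
distribution models; they use *bioclimatic indicators* — scalar summaries of
the intra-annual temperature and precipitation regime such as the annual
mean temperature, the precipitation of the wettest quarter, or the warmth
available in the growing season. `bioclimind` computes the full 35-indicator
family from daily mean/maximum/minimum temperature (Tg, Tx, Tn) and
precipitation (P) grids: the WorldClim/ANUCLIM set (Bio1–Bio19), the
Rivas-Martínez ombrothermic and thermicity indices, the Kira warmth and
coldness indices, the Ellenberg quotient, a continentality index, and
temperature-based potential evapotranspiration after Hargreaves–Samani and
Thornthwaite (Bio34–Bio35).

Two features distinguish this family from naive climatologies:

* **Per-year extremes.** The warmest/coldest/wettest/driest month or quarter
  is identified separately in each year of the period; the statistic of the
  selected month/window is then averaged across years. For example

  Bio16 = (1/Y) Σ_y max over windows *q* centered in year *y* of P(q, y),

  where the candidate windows are all three-consecutive-month runs whose
  central month falls in year *y* (so a Dec–Jan–Feb window belongs to the
  year of its January).
* **Calendar awareness.** Climate-model forcing comes on standard, no-leap
  and 360-day calendars; all monthly and quarter logic is calendar-generic.

The package also reads/writes the per-indicator NetCDF layout of the
CMCC-BioClimInd-style datasets (file names `BIO{x}_{SOURCE}[_{RCP}]_{yyyy}_{zz}.nc`,
805 files under the full historical + 11-member future coverage) and derives
ensemble-mean anomaly (%) and relative-standard-deviation maps across
simulation members.

## Worked example

```python
import numpy as np
from bioclimind import (SyntheticClimateConfig, generate_daily_climate,
                        compute_all, INDICATOR_INFO)

cfg = SyntheticClimateConfig(
    lat=np.array([45.0]), lon=np.array([0.0]),
    years=range(1990, 1996), calendar="noleap", seed=42)
series = generate_daily_climate(cfg)      # or climate_io.read_daily_series(...)
out = compute_all(series, [1, 4, 5, 6, 12, 13, 16, 23, 34, 35])
for code, arr in out.items():
    name, units = INDICATOR_INFO[code]
    print(f"Bio{code:<2} {name:<45} {arr[0,0]:9.2f} {units}")
```

```
Bio1  Annual mean temperature                           16.45 degC
Bio4  Temperature seasonality                            7.67 degC
Bio5  Max temperature of warmest month                  31.35 degC
Bio6  Min temperature of coldest month                   1.69 degC
Bio12 Annual precipitation                            1060.90 mm
Bio13 Precipitation of wettest month                   159.58 mm
Bio16 Precipitation of wettest quarter                 387.89 mm
Bio23 Ombrothermic index                                53.90 mm/degC
Bio34 Potential evapotranspiration (Hargreaves-Samani)    949.71 mm
Bio35 Potential evapotranspiration (Thornthwaite)      914.92 mm
```

This is a synthetic mid-latitude cell (seasonal cycle peaking in July,
stochastic precipitation). Bio1 is the day-weighted mean temperature over
the six years; Bio5/Bio6 show the ~30 °C annual envelope of monthly
extremes; Bio16 > Bio13 because a quarter contains its wettest month; Bio23
(ten times precipitation over the temperature sum of months above 0 °C)
marks a humid regime; the two PET estimates agree to within a few percent,
as expected for a temperate cell.

The same computation from the shell, starting from CF-style forcing files
(Kelvin and kg m⁻² s⁻¹ are converted on read):

```sh
bioclimind synth --years 5 --out forcing.nc
bioclimind compute --tg forcing.nc --tx forcing.nc --tn forcing.nc \
    --pr forcing.nc --period 2000-2004 --codes all --out-dir out/
bioclimind ensemble --reference out/BIO12_HIST_2000_04.nc \
    --member m1.nc --member m2.nc --op rsd --out rsd.nc
bioclimind inspect out/BIO12_HIST_2000_04.nc
```

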