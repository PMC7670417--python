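"""Independent straight-loop reference implementation for one grid cell.

Deliberately naive: explicit Python loops over days, months and years, no
shared code with the package.  Used by the tests as the oracle for the
indicator engine and the PET formulas.  Tie-breaks mirror the documented
rules: earliest calendar month / earliest window center wins.
"""

import math

NOLEAP = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
LEAP = [31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]


def month_lengths(year, calendar):
    if calendar == "360_day":
        return [30] * 12
    if calendar == "noleap":
        return list(NOLEAP)
    leap = year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
    return list(LEAP) if leap else list(NOLEAP)


def monthly_aggregates(daily, years, calendar):
    """Per (year, month) dict of aggregates from per-day dicts.

    ``daily`` is a list of dicts with keys tg, tx, tn, p, one per day, in
    order.  Returns a list (one per year) of lists (12) of dicts with keys
    tgm, txm, tnm, ptot, nd — or None if any day of the month is NaN.
    """
    out = []
    i = 0
    for y in years:
        months = []
        for m in range(12):
            nd = month_lengths(y, calendar)[m]
            chunk = daily[i:i + nd]
            i += nd
            vals = {k: [d[k] for d in chunk] for k in ("tg", "tx", "tn", "p")}
            if any(math.isnan(v) for vs in vals.values() for v in vs):
                months.append(None)
                continue
            months.append({
                "tgm": sum(vals["tg"]) / nd, "txm": sum(vals["tx"]) / nd,
                "tnm": sum(vals["tn"]) / nd, "ptot": sum(vals["p"]), "nd": nd,
            })
        out.append(months)
    return out


def _extreme_month(months_by_year, key, mode):
    """Per-year (index, aggregates) of the extreme month; earliest wins ties."""
    results = []
    for months in months_by_year:
        best = None
        for m in range(12):
            agg = months[m]
            if agg is None:
                continue
            v = agg[key]
            if best is None or (mode == "max" and v > best[1]) or (mode == "min" and v < best[1]):
                best = (m, v, agg)
        results.append(best)
    return results


def _quarters(months_by_year, years):
    """All complete 3-month windows as flat-index triples with stats."""
    flat = [m for months in months_by_year for m in months]
    n = len(flat)
    windows = {}
    for k in range(1, n - 1):
        trio = [flat[k - 1], flat[k], flat[k + 1]]
        if any(t is None for t in trio):
            continue
        nd = sum(t["nd"] for t in trio)
        windows[k] = {
            "p": sum(t["ptot"] for t in trio),
            "tg": sum(t["tgm"] * t["nd"] for t in trio) / nd,
        }
    return windows


def _extreme_quarter(months_by_year, years, key, mode):
    """Per-year best window among the 12 centered in that year."""
    windows = _quarters(months_by_year, years)
    results = []
    for iy in range(len(years)):
        best = None
        for m in range(12):
            k = iy * 12 + m
            if k not in windows:
                continue
            v = windows[k][key]
            if best is None or (mode == "max" and v > best[1]) or (mode == "min" and v < best[1]):
                best = (k, v, windows[k])
        results.append(best)
    return results


def _mean(xs):
    xs = [x for x in xs if x is not None]
    return sum(xs) / len(xs) if xs else float("nan")


# --- solar geometry & PET (independent FAO-56 / textbook transcription) ----

def solar_declination(doy, year_length):
    return 0.409 * math.sin(2 * math.pi * doy / year_length - 1.39)


def sunset_hour_angle(lat_deg, decl):
    x = -math.tan(math.radians(lat_deg)) * math.tan(decl)
    x = min(1.0, max(-1.0, x))
    return math.acos(x)


def ref_day_length(lat_deg, month, calendar, year=2001):
    ml = month_lengths(year, calendar)
    doy = sum(ml[:month - 1]) + ml[month - 1] / 2.0
    decl = solar_declination(doy, sum(ml))
    return 24.0 / math.pi * sunset_hour_angle(lat_deg, decl)


def ref_ra(lat_deg, month, calendar, year=2001):
    ml = month_lengths(year, calendar)
    doy = sum(ml[:month - 1]) + ml[month - 1] / 2.0
    yl = sum(ml)
    decl = solar_declination(doy, yl)
    ws = sunset_hour_angle(lat_deg, decl)
    dr = 1 + 0.033 * math.cos(2 * math.pi * doy / yl)
    phi = math.radians(lat_deg)
    ra = (24 * 60 / math.pi) * 0.0820 * dr * (
        ws * math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.sin(ws))
    return 0.408 * max(ra, 0.0)


def ref_hargreaves_month(tgm, tdm, lat_deg, month, year, calendar):
    """Monthly Hargreaves-Samani PET total (mm)."""
    ra = ref_ra(lat_deg, month, calendar, year)
    nd = month_lengths(year, calendar)[month - 1]
    return 0.0023 * ra * max(tgm + 17.8, 0.0) * math.sqrt(max(tdm, 0.0)) * nd


def ref_thornthwaite_year(tg_months, lat_deg, year, calendar):
    """Twelve monthly Thornthwaite PET totals (mm) for one year."""
    heat = sum((t / 5.0) ** 1.514 for t in tg_months if t > 0)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    out = []
    for m, t in enumerate(tg_months, start=1):
        if t <= 0 or heat <= 0:
            out.append(0.0)
            continue
        nd = month_lengths(year, calendar)[m - 1]
        n = ref_day_length(lat_deg, m, calendar, year)
        out.append(16.0 * (10.0 * t / heat) ** a * (n / 12.0) * (nd / 30.0))
    return out


# --- full indicator set -----------------------------------------------------

def reference_indicators(daily, years, calendar, lat_deg):
    """Bio1..Bio35 for one cell, by explicit loops.  NaN-free input assumed
    complete; months containing NaN days are treated as missing."""
    years = list(years)
    mby = monthly_aggregates(daily, years, calendar)
    out = {}

    # annual means
    i = 0
    tg_yearly, p_yearly = [], []
    for y in years:
        yl = sum(month_lengths(y, calendar))
        days = daily[i:i + yl]
        i += yl
        tg_yearly.append(sum(d["tg"] for d in days) / yl)
        p_yearly.append(sum(d["p"] for d in days))
    out[1] = _mean(tg_yearly)
    out[2] = _mean([d["tx"] - d["tn"] for d in daily])
    out[12] = _mean(p_yearly)

    # climatological monthly vectors
    tg_clim = [_mean([mby[iy][m]["tgm"] if mby[iy][m] else None for iy in range(len(years))])
               for m in range(12)]
    p_clim = [_mean([mby[iy][m]["ptot"] if mby[iy][m] else None for iy in range(len(years))])
              for m in range(12)]
    mu_t = sum(tg_clim) / 12
    out[4] = math.sqrt(sum((v - mu_t) ** 2 for v in tg_clim) / 12)
    mu_p = sum(p_clim) / 12
    out[15] = 100.0 * math.sqrt(sum((v - mu_p) ** 2 for v in p_clim) / 12) / (mu_p + 1.0)

    # extreme months
    warm = _extreme_month(mby, "txm", "max")
    cold = _extreme_month(mby, "tnm", "min")
    wet = _extreme_month(mby, "ptot", "max")
    dry = _extreme_month(mby, "ptot", "min")
    out[5] = _mean([b[2]["txm"] if b else None for b in warm])
    out[6] = _mean([b[2]["tnm"] if b else None for b in cold])
    out[13] = _mean([b[2]["ptot"] if b else None for b in wet])
    out[14] = _mean([b[2]["ptot"] if b else None for b in dry])
    out[28] = _mean([b[2]["tgm"] if b else None for b in warm])
    out[29] = _mean([b[2]["tgm"] if b else None for b in cold])
    out[30] = _mean([b[2]["tgm"] if b else None for b in dry])
    out[31] = _mean([b[2]["tgm"] if b else None for b in wet])
    out[7] = out[5] - out[6]
    out[3] = 100.0 * out[2] / out[7] if out[7] != 0 else float("nan")
    out[27] = out[28] - out[29]
    out[32] = 10.0 * (out[1] + out[5] + out[6])

    # extreme quarters
    for codes, key, mode in (((8, 16), "p", "max"), ((9, 17), "p", "min"),
                             ((10, 18), "tg", "max"), ((11, 19), "tg", "min")):
        best = _extreme_quarter(mby, years, key, mode)
        out[codes[0]] = _mean([b[2]["tg"] if b else None for b in best])
        out[codes[1]] = _mean([b[2]["p"] if b else None for b in best])

    # climatological threshold sums
    out[21] = sum(t for t in tg_clim if t > 0)
    out[22] = sum(tg_clim)
    out[24] = sum(p for p, t in zip(p_clim, tg_clim) if t > 0)
    out[25] = sum(t for t in tg_clim if t < 5)
    out[26] = sum(t for t in tg_clim if t > 5)
    out[20] = 1000.0 * out[28] / out[12] if out[12] != 0 else float("nan")
    out[23] = 10.0 * out[24] / out[21] if out[21] > 0 else float("nan")
    p_mjja = sum(p_clim[4:8])
    t_mjja = sum(tg_clim[4:8])
    out[33] = 10.0 * p_mjja / t_mjja if t_mjja > 0 else float("nan")

    # PET
    har_yearly, tho_yearly = [], []
    i = 0
    for iy, y in enumerate(years):
        yl = sum(month_lengths(y, calendar))
        days = daily[i:i + yl]
        i += yl
        # monthly diurnal ranges
        tds, j = [], 0
        for m in range(12):
            nd = month_lengths(y, calendar)[m]
            chunk = days[j:j + nd]
            j += nd
            tds.append(sum(d["tx"] - d["tn"] for d in chunk) / nd)
        months = mby[iy]
        if any(mo is None for mo in months):
            har_yearly.append(None)
            tho_yearly.append(None)
            continue
        har_yearly.append(sum(
            ref_hargreaves_month(months[m]["tgm"], tds[m], lat_deg, m + 1, y, calendar)
            for m in range(12)))
        tho_yearly.append(sum(
            ref_thornthwaite_year([mo["tgm"] for mo in months], lat_deg, y, calendar)))
    for code, yearly in ((34, har_yearly), (35, tho_yearly)):
        valid = [v for v in yearly if v is not None]
        if len(valid) / len(yearly) >= 0.8:
            out[code] = sum(valid) / len(valid)
        else:
            out[code] = float("nan")
    return out
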