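"""Yearly peak-timing extraction and climate covariates.

A monthly abundance series cannot resolve timing below the month, so the
yearly phenology statistic is the mid-month day-of-year (the 15th) of the
month with the maximum abundance.  Because many estuarine taxa peak near the
calendar boundary (December–January), raw day-of-year values are *unwrapped*
on the circle before any linear trend is estimated: a drift from late
December into early January must appear as +15 days, not −350.

Climate enters at two scales: the annual mean of the covariate, and a
seasonal mean over a window centred on the month of peak abundance.
"""

from __future__ import annotations

import calendar

import numpy as np
import pandas as pd

YEAR_DAYS = 365.25  # circle circumference used for the circular mean


def year_length(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


def month_mid_doy(year: int, month: int) -> int:
    """Day-of-year of the 15th of ``month`` (leap-aware)."""
    days_before = sum(calendar.monthrange(year, m)[1] for m in range(1, month))
    return days_before + 15


def peak_day(months: np.ndarray, year: int, *, min_months: int = 6
             ) -> tuple[int, int] | None:
    """Peak (day-of-year, month) of one year's 12-slot abundance vector.

    Returns None (missing-record signal) when fewer than ``min_months``
    entries are observed or when no month has positive abundance (an all-zero
    year has no defined peak).  Ties break to the earliest month.
    """
    v = np.asarray(months, dtype=float)
    if v.shape != (12,):
        raise ValueError("expected a 12-slot monthly vector")
    observed = np.isfinite(v)
    if observed.sum() < min_months:
        return None
    if np.nanmax(v[observed]) <= 0:
        return None
    filled = np.where(observed, v, -np.inf)
    month = int(np.argmax(filled)) + 1  # argmax takes the first maximum
    return month_mid_doy(year, month), month


def unwrap_peaks(doys, years) -> tuple[np.ndarray, np.ndarray]:
    """Unwrap yearly peak day-of-year values across the calendar boundary.

    Each raw value is shifted by an integer multiple of its own year's length
    so that it lands within half a year of the series' circular mean peak
    date; the whole series is then shifted by the minimal non-negative
    multiple of 365 days needed to keep every adjusted value >= 1, so that
    series away from the boundary come back unchanged.

    Returns (adjusted, offsets) with ``adjusted = raw + offsets``.
    """
    doys = np.asarray(doys, dtype=float)
    years = np.asarray(years, dtype=int)
    if doys.size < 2:
        return doys.copy(), np.zeros_like(doys)
    lengths = np.array([year_length(y) for y in years], dtype=float)

    theta = 2 * np.pi * doys / lengths
    mean_angle = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    center = (mean_angle / (2 * np.pi)) * YEAR_DAYS % YEAR_DAYS

    for bump in range(4):
        target = center + bump * 365.0
        k = np.round((target - doys) / lengths)
        adjusted = doys + k * lengths
        if adjusted.min() >= 1:
            break
    offsets = adjusted - doys
    return adjusted, offsets


def annual_covariate(climate: pd.DataFrame, station, year: int,
                     variable: str) -> tuple[float, int]:
    """Mean of a climate variable over the months available in one year.

    Returns (mean, months_used); (nan, 0) when no month is observed.
    """
    rows = climate[(climate["station"] == station) & (climate["year"] == year)]
    vals = rows[variable].dropna()
    if vals.empty:
        return float("nan"), 0
    return float(vals.mean()), int(len(vals))


def seasonal_covariate(climate: pd.DataFrame, station, year: int,
                       peak_month: int, variable: str, *,
                       half_window: int = 1) -> float:
    """Mean of a climate variable around the month of peak abundance.

    The window is ``peak_month ± half_window`` months, wrapping across the
    year boundary within the same calendar year (a January peak averages
    December, January and February of that year).  NaN when no month in the
    window is observed.
    """
    months = {((peak_month - 1 + d) % 12) + 1
              for d in range(-half_window, half_window + 1)}
    rows = climate[(climate["station"] == station)
                   & (climate["year"] == year)
                   & (climate["month"].isin(months))]
    vals = rows[variable].dropna()
    return float(vals.mean()) if not vals.empty else float("nan")


def _annual_means(climate: pd.DataFrame) -> pd.DataFrame:
    out = (climate.groupby(["station", "year"])[["temperature", "salinity"]]
           .mean().reset_index()
           .rename(columns={"temperature": "annual_temp",
                            "salinity": "annual_sal"}))
    return out


def _seasonal_lookup(climate: pd.DataFrame, half_window: int) -> pd.DataFrame:
    """Windowed means for every (station, year, centre-month) combination."""
    frames = []
    for centre in range(1, 13):
        months = [((centre - 1 + d) % 12) + 1
                  for d in range(-half_window, half_window + 1)]
        sub = climate[climate["month"].isin(months)]
        agg = (sub.groupby(["station", "year"])[["temperature", "salinity"]]
               .mean().reset_index())
        agg["peak_month"] = centre
        frames.append(agg)
    out = pd.concat(frames, ignore_index=True)
    return out.rename(columns={"temperature": "seasonal_temp",
                               "salinity": "seasonal_sal"})


def extract_phenology(monitoring: pd.DataFrame, climate: pd.DataFrame, *,
                      min_months_per_year: int = 6, unwrap: bool = True,
                      seasonal_half_window: int = 1) -> pd.DataFrame:
    """Build the per-(taxon, station, year) phenology table.

    For each series and year: the peak day-of-year and month (mid-month
    convention), the number of observed months, the annual-mean temperature
    and salinity, and the seasonal means around the peak month.  With
    ``unwrap=True`` (default) peak days are circularly unwrapped per series;
    ``peak_doy_offset`` records the applied adjustment so that
    ``peak_doy - peak_doy_offset`` is always the raw calendar value.
    """
    wide = monitoring.pivot_table(index=["taxon", "station", "year"],
                                  columns="month", values="value",
                                  aggfunc="first")
    wide = wide.reindex(columns=range(1, 13))
    meta = (monitoring[["taxon", "station", "estuary", "region",
                        "trophic_group"]]
            .drop_duplicates(subset=["taxon", "station"]))

    records = []
    for (taxon, station, year), row in wide.iterrows():
        res = peak_day(row.to_numpy(), int(year), min_months=min_months_per_year)
        if res is None:
            continue
        doy, month = res
        records.append({
            "taxon": taxon, "station": station, "year": int(year),
            "peak_doy_raw": doy, "peak_month": month,
            "n_months_observed": int(np.isfinite(row.to_numpy(dtype=float)).sum()),
        })
    if not records:
        return pd.DataFrame(columns=[
            "taxon", "station", "estuary", "region", "trophic_group", "year",
            "peak_doy", "peak_doy_raw", "peak_doy_offset", "peak_month",
            "n_months_observed", "annual_temp", "annual_sal",
            "seasonal_temp", "seasonal_sal"])
    pheno = pd.DataFrame.from_records(records)

    if unwrap:
        parts = []
        for _, grp in pheno.groupby(["taxon", "station"], sort=False):
            grp = grp.sort_values("year").copy()
            adjusted, offsets = unwrap_peaks(grp["peak_doy_raw"].to_numpy(),
                                             grp["year"].to_numpy())
            grp["peak_doy"] = adjusted
            grp["peak_doy_offset"] = offsets
            parts.append(grp)
        pheno = pd.concat(parts, ignore_index=True)
    else:
        pheno["peak_doy"] = pheno["peak_doy_raw"].astype(float)
        pheno["peak_doy_offset"] = 0.0

    pheno = pheno.merge(_annual_means(climate), on=["station", "year"],
                        how="left")
    pheno = pheno.merge(_seasonal_lookup(climate, seasonal_half_window),
                        on=["station", "year", "peak_month"], how="left")
    pheno = pheno.merge(meta, on=["taxon", "station"], how="left")
    cols = ["taxon", "station", "estuary", "region", "trophic_group", "year",
            "peak_doy", "peak_doy_raw", "peak_doy_offset", "peak_month",
            "n_months_observed", "annual_temp", "annual_sal",
            "seasonal_temp", "seasonal_sal"]
    return pheno[cols].sort_values(["taxon", "station", "year"]).reset_index(drop=True)
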