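"""Ingestion and validation of long-format monitoring and water-quality tables.

The analysis consumes two kinds of tables:

* a *monitoring* table — one row per (taxon, station, year, month) holding a
  non-negative abundance or biomass value, tagged with estuary, region and
  trophic group;
* a *climate* table — one row per (station, year, month) holding temperature
  (°C) and salinity (practical salinity units), either possibly missing.

Everything downstream (peak-timing extraction, effect sizes, the
meta-regression) assumes monthly series, so validation enforces monthly keys
and rejects rows that cannot enter the analysis, with a per-row report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MONITORING_COLUMNS = [
    "estuary", "region", "station", "taxon", "trophic_group",
    "year", "month", "value", "value_kind",
]
CLIMATE_COLUMNS = ["station", "year", "month", "temperature", "salinity"]

TROPHIC_GROUPS = frozenset({"fish", "zooplankton", "phytoplankton"})
VALUE_KINDS = frozenset({"abundance", "biomass"})

MONITORING_KEY = ["taxon", "station", "year", "month"]
CLIMATE_KEY = ["station", "year", "month"]


class SchemaError(ValueError):
    """A required column is absent from the input table."""


class DuplicateKeyError(ValueError):
    """The input table holds more than one row for a series key."""

    def __init__(self, message: str, offenders: pd.DataFrame):
        super().__init__(message)
        self.offenders = offenders


class JoinError(ValueError):
    """Monitoring and climate tables share no station labels."""


@dataclass
class IngestReport:
    """Per-row validation outcome of a read operation."""

    n_input: int = 0
    n_kept: int = 0
    rejected: list[dict] = field(default_factory=list)

    def reject(self, index, reason: str) -> None:
        self.rejected.append({"row": int(index), "reason": reason})


def _apply_schema(df: pd.DataFrame, schema: dict[str, str] | None,
                  required: list[str]) -> pd.DataFrame:
    """Rename columns via a {canonical: actual} mapping and check presence."""
    if schema:
        missing_src = [v for v in schema.values() if v not in df.columns]
        if missing_src:
            raise SchemaError(f"mapped columns absent from file: {missing_src}")
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    return df


def _check_duplicates(df: pd.DataFrame, key: list[str], what: str) -> None:
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        offenders = df.loc[dup, key].drop_duplicates()
        raise DuplicateKeyError(
            f"{int(dup.sum())} {what} rows share {len(offenders)} duplicated "
            f"keys {key}; first offenders:\n{offenders.head(10)}",
            offenders,
        )


def read_monitoring(path, schema: dict[str, str] | None = None, *,
                    average_replicates: bool = False
                    ) -> tuple[pd.DataFrame, IngestReport]:
    """Read and validate a long-format monitoring CSV.

    Parameters
    ----------
    path : path-like or file-like
        CSV with a header row (UTF-8).
    schema : dict, optional
        Mapping of canonical column name -> column name in the file.
    average_replicates : bool
        If True, multiple samples within a (taxon, station, year, month)
        cell (e.g. replicate tows) are averaged before validation.
        If False (default), duplicated keys raise :class:`DuplicateKeyError`.

    Returns
    -------
    (table, report)
        ``table`` holds the validated rows in canonical column order;
        ``report`` lists every rejected row with its reason.
    """
    raw = pd.read_csv(path) if not isinstance(path, pd.DataFrame) else path.copy()
    df = _apply_schema(raw, schema, MONITORING_COLUMNS)[MONITORING_COLUMNS]
    report = IngestReport(n_input=len(df))

    df["year"] = pd.to_numeric(df["year"], errors="coerce")
    df["month"] = pd.to_numeric(df["month"], errors="coerce")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")

    if average_replicates:
        grouped = df.groupby(MONITORING_KEY, as_index=False, dropna=False)
        df = grouped.agg({
            "estuary": "first", "region": "first", "trophic_group": "first",
            "value_kind": "first", "value": "mean",
        })[MONITORING_COLUMNS]

    ok = pd.Series(True, index=df.index)

    bad_month = ~(df["month"].between(1, 12) & (df["month"] % 1 == 0))
    for i in df.index[bad_month]:
        report.reject(i, f"month out of range: {df.loc[i, 'month']}")
    ok &= ~bad_month

    bad_year = df["year"].isna()
    for i in df.index[bad_year & ok]:
        report.reject(i, "year missing or non-numeric")
    ok &= ~bad_year

    neg = df["value"] < 0  # NaN (missing) compares False and is allowed
    for i in df.index[neg & ok]:
        report.reject(i, f"negative value: {df.loc[i, 'value']}")
    ok &= ~neg

    bad_group = ~df["trophic_group"].isin(TROPHIC_GROUPS)
    for i in df.index[bad_group & ok]:
        report.reject(i, f"unknown trophic_group: {df.loc[i, 'trophic_group']}")
    ok &= ~bad_group

    bad_kind = ~df["value_kind"].isin(VALUE_KINDS)
    for i in df.index[bad_kind & ok]:
        report.reject(i, f"unknown value_kind: {df.loc[i, 'value_kind']}")
    ok &= ~bad_kind

    df = df[ok].reset_index(drop=True)
    df["year"] = df["year"].astype(int)
    df["month"] = df["month"].astype(int)
    _check_duplicates(df, MONITORING_KEY, "monitoring")
    report.n_kept = len(df)
    return df, report


def read_climate(path, schema: dict[str, str] | None = None
                 ) -> tuple[pd.DataFrame, IngestReport]:
    """Read and validate a water-quality CSV (temperature, salinity)."""
    raw = pd.read_csv(path) if not isinstance(path, pd.DataFrame) else path.copy()
    df = _apply_schema(raw, schema, CLIMATE_COLUMNS)[CLIMATE_COLUMNS]
    report = IngestReport(n_input=len(df))

    df["year"] = pd.to_numeric(df["year"], errors="coerce")
    df["month"] = pd.to_numeric(df["month"], errors="coerce")
    for var in ("temperature", "salinity"):
        df[var] = pd.to_numeric(df[var], errors="coerce")

    ok = df["month"].between(1, 12) & (df["month"] % 1 == 0) & df["year"].notna()
    for i in df.index[~ok]:
        report.reject(i, "month out of [1,12] or year missing")
    df = df[ok].reset_index(drop=True)
    df["year"] = df["year"].astype(int)
    df["month"] = df["month"].astype(int)
    _check_duplicates(df, CLIMATE_KEY, "climate")
    report.n_kept = len(df)
    return df, report


def filter_series(table: pd.DataFrame, min_years: int = 10,
                  min_months_per_year: int = 6
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep only (taxon, station) series long enough for trend estimation.

    A year *qualifies* when it has at least ``min_months_per_year`` months
    with a non-missing value; a series is kept when it has at least
    ``min_years`` qualifying years.  Multidecadal series are the point of the
    analysis: short series cannot separate a linear drift in peak timing
    from interannual noise.

    Returns the filtered table and a log DataFrame (one row per series with
    ``qualifying_years`` and ``kept``).
    """
    if table.empty:
        log = pd.DataFrame(columns=["taxon", "station", "qualifying_years", "kept"])
        return table.copy(), log

    observed = table[table["value"].notna()]
    months_per_year = (observed.groupby(["taxon", "station", "year"])["month"]
                       .nunique())
    qualifying = (months_per_year >= min_months_per_year)
    qual_years = qualifying.groupby(level=["taxon", "station"]).sum()

    all_series = table[["taxon", "station"]].drop_duplicates()
    log = all_series.merge(
        qual_years.rename("qualifying_years").reset_index(),
        on=["taxon", "station"], how="left",
    )
    log["qualifying_years"] = log["qualifying_years"].fillna(0).astype(int)
    log["kept"] = log["qualifying_years"] >= min_years

    keep_keys = log.loc[log["kept"], ["taxon", "station"]]
    out = table.merge(keep_keys, on=["taxon", "station"], how="inner")
    return out.reset_index(drop=True), log


def join_climate(monitoring: pd.DataFrame, climate: pd.DataFrame
                 ) -> tuple[pd.DataFrame, float]:
    """Left-join climate measurements onto monitoring rows.

    Joins on (station, year, month); unmatched climate rows are ignored.
    Returns the joined table and the fraction of monitoring rows that found
    a climate row.  Raises :class:`JoinError` when the station sets are
    disjoint, which indicates mismatched inputs rather than sparse data.
    """
    shared = set(monitoring["station"]) & set(climate["station"])
    if not shared:
        raise JoinError("monitoring and climate tables share no stations")
    out = monitoring.merge(climate, on=CLIMATE_KEY, how="left",
                           validate="many_to_one")
    matched = out["temperature"].notna() | out["salinity"].notna()
    match_rate = float(matched.mean()) if len(out) else 0.0
    return out, match_rate


def write_monitoring(table: pd.DataFrame, path) -> None:
    """Write a validated monitoring table in canonical column order."""
    table[MONITORING_COLUMNS].to_csv(path, index=False)


def write_climate(table: pd.DataFrame, path) -> None:
    table[CLIMATE_COLUMNS].to_csv(path, index=False)
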