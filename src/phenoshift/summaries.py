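"""Downstream comparison statistics on slope and verdict tables.

These are the classical tests run after the meta-regression: a factorial
ANOVA asking whether climate sensitivity (PC slopes) differs by covariate,
estuary and trophic group; a Brown–Forsythe (median-centred Levene) test of
whether the spread of phenological trends (PT slopes) differs between
trophic groups; Pearson chi-squared tests on tracking-rate contingency
tables; and per-stratum abundance-vs-year trends cross-tabulated against
the tracking verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .effect_sizes import fisher_z, sampling_variance


def anova_factorial(values, factors: pd.DataFrame, *,
                    interactions: bool = True) -> pd.DataFrame:
    """Factorial ANOVA (type-II sums of squares) on slope estimates.

    Parameters
    ----------
    values : array-like
        The response (e.g. PC slope estimates, one per stratum).
    factors : DataFrame
        One categorical column per factor, aligned with ``values``.
    interactions : bool
        Include all interaction terms (default) or main effects only.

    Terms whose cells are empty (inestimable) are dropped with a warning.
    Returns the ANOVA table with sum_sq, df, F and PR(>F) per term.
    """
    df = factors.copy()
    for c in df.columns:
        if df[c].nunique() < 2:
            warnings.warn(f"factor {c!r} has a single level; dropped")
            df = df.drop(columns=c)
    if df.shape[1] == 0:
        raise ValueError("no usable factors (need >= 2 levels each)")
    df = df.astype(str)
    df["response"] = np.asarray(values, dtype=float)
    op = " * " if interactions else " + "
    formula = "response ~ " + op.join(f"C({c})" for c in factors.columns
                                      if c in df.columns)
    model = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on 0-df terms
        table = sm.stats.anova_lm(model, typ=2)
    # drop inestimable terms (NaN F with zero df)
    bad = table["df"] <= 0
    if bad.any():
        warnings.warn(f"dropped inestimable terms: {list(table.index[bad])}")
        table = table[~bad]
    return table


def levene_test(values, groups, *, center: str = "median"
                ) -> tuple[float, float]:
    """Homogeneity of variances across groups (Brown–Forsythe by default).

    Groups with fewer than 2 values are dropped with a warning; fewer than
    two usable groups is an error.  Returns (W statistic, p-value).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = []
    for g in pd.unique(groups):
        sample = values[groups == g]
        sample = sample[np.isfinite(sample)]
        if len(sample) < 2:
            warnings.warn(f"group {g!r} has < 2 values; dropped")
            continue
        samples.append(sample)
    if len(samples) < 2:
        raise ValueError("need at least two groups with >= 2 values")
    stat, p = stats.levene(*samples, center=center)
    return float(stat), float(p)


def chisq_tracking(counts) -> dict:
    """Pearson chi-squared test (no continuity correction) on a count table.

    Returns a dict with statistic, df, pvalue and the expected counts;
    warns when any expected count is below 5.  A zero marginal row or
    column is an error (the test is undefined).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a 2×2 or larger contingency table")
    if (table < 0).any():
        raise ValueError("negative counts")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("zero marginal row or column")
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("some expected counts < 5; chi-squared approximation "
                      "may be poor")
    return {"statistic": float(res.statistic), "df": int(res.dof),
            "pvalue": float(res.pvalue), "expected": res.expected_freq}


@dataclass
class AbundanceTrend:
    group: dict
    trend_r: float
    n: int
    ci_low: float
    ci_high: float
    direction: str               # increasing / decreasing / none
    degenerate: bool = False


def abundance_trend(years, annual_abundance, *, group: dict | None = None,
                    level: float = 0.95) -> AbundanceTrend:
    """Trend of annual aggregate abundance: Pearson r vs year with Fisher CI.

    Direction is ``increasing``/``decreasing`` when the Fisher-z CI on r
    excludes zero, else ``none``.  Constant abundance gives r = 0 with a
    degenerate flag.
    """
    years = np.asarray(years, dtype=float)
    ab = np.asarray(annual_abundance, dtype=float)
    ok = np.isfinite(years) & np.isfinite(ab)
    years, ab = years[ok], ab[ok]
    n = len(years)
    if n < 4:
        raise ValueError(f"need >= 4 years of annual abundance, got {n}")
    if np.std(ab) == 0 or np.std(years) == 0:
        return AbundanceTrend(group=dict(group or {}), trend_r=0.0, n=n,
                              ci_low=float("nan"), ci_high=float("nan"),
                              direction="none", degenerate=True)
    r = float(np.corrcoef(years, ab)[0, 1])
    z = fisher_z(r)
    se = np.sqrt(sampling_variance(n))
    q = stats.norm.ppf(0.5 + level / 2)
    lo, hi = np.tanh(z - q * se), np.tanh(z + q * se)
    if lo > 0:
        direction = "increasing"
    elif hi < 0:
        direction = "decreasing"
    else:
        direction = "none"
    return AbundanceTrend(group=dict(group or {}), trend_r=r, n=n,
                          ci_low=float(lo), ci_high=float(hi),
                          direction=direction)


def abundance_trends(monitoring: pd.DataFrame) -> pd.DataFrame:
    """Per-(taxon, station) abundance trend from annual mean abundance."""
    annual = (monitoring.groupby(["taxon", "station", "year"])["value"]
              .mean().reset_index())
    rows = []
    for (taxon, station), grp in annual.groupby(["taxon", "station"]):
        if len(grp) < 4:
            continue
        t = abundance_trend(grp["year"], grp["value"],
                            group={"taxon": taxon, "station": station})
        rows.append({"taxon": taxon, "station": station, "trend_r": t.trend_r,
                     "n": t.n, "ci_low": t.ci_low, "ci_high": t.ci_high,
                     "direction": t.direction, "degenerate": t.degenerate})
    return pd.DataFrame(rows)


def crosstab_tracking_abundance(verdicts: pd.DataFrame,
                                trends: pd.DataFrame) -> dict:
    """Cross-tabulate tracking status against abundance-trend direction.

    Both inputs must carry (taxon, station) keys.  Returns the contingency
    table and, when the table is at least 2×2, the chi-squared result
    (otherwise the test is skipped and noted).
    """
    joined = verdicts.merge(trends, on=["taxon", "station"], how="inner",
                            suffixes=("", "_trend"))
    if joined.empty:
        raise ValueError("verdicts and trends share no (taxon, station) keys")
    table = pd.crosstab(joined["status"], joined["direction_trend"]
                        if "direction_trend" in joined.columns
                        else joined["direction"])
    result = {"table": table, "test": None, "note": ""}
    if table.shape[0] >= 2 and table.shape[1] >= 2:
        result["test"] = chisq_tracking(table.to_numpy())
    else:
        result["note"] = ("contingency table is degenerate "
                          f"({table.shape[0]}×{table.shape[1]}); test skipped")
    return result
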