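#!/usr/bin/env python
"""Comparison statistics across estuaries, covariates and trophic groups.

Three-way ANOVA (type II) on climate-sensitivity (PC) slopes, the
Brown–Forsythe test on the spread of phenological trends (PT), chi-squared
tests on tracking rates, and the cross-tabulation of tracking status
against abundance trends.
"""

import json
from pathlib import Path

import pandas as pd

from phenoshift import ingest, summaries

ROOT = Path(__file__).resolve().parents[1] / "results"
PRESETS = ("sanfrancisco-like", "chesapeake-like", "massbay-like")


def main() -> None:
    slopes, verdicts = [], []
    for name in PRESETS:
        for covariate in ("temperature", "salinity"):
            s = pd.read_csv(ROOT / f"{name}_{covariate}_slopes.csv")
            v = pd.read_csv(ROOT / f"{name}_{covariate}_verdicts.csv")
            for df in (s, v):
                df["estuary"] = name
                df["covariate"] = covariate
            s["trophic_group"] = s["taxon"].str.rsplit("_", n=1).str[0]
            slopes.append(s)
            verdicts.append(v)
    slopes = pd.concat(slopes, ignore_index=True)
    verdicts = pd.concat(verdicts, ignore_index=True)

    report = {}
    anova = summaries.anova_factorial(
        slopes["PC_estimate"],
        slopes[["covariate", "estuary", "trophic_group"]])
    report["anova_PC"] = anova.reset_index().to_dict("records")
    print("three-way ANOVA on PC slopes:")
    print(anova.round(4).to_string())

    w, p = summaries.levene_test(slopes["PT_estimate"],
                                 slopes["trophic_group"])
    report["levene_PT"] = {"W": w, "p": p}
    print(f"\nBrown–Forsythe on PT slopes by trophic group: "
          f"W = {w:.3f}, p = {p:.4f}")

    for covariate in ("temperature", "salinity"):
        sub = verdicts[verdicts["covariate"] == covariate]
        counts = pd.crosstab(sub["estuary"], sub["tracking"])
        chi = summaries.chisq_tracking(counts.to_numpy())
        report[f"chisq_tracking_{covariate}"] = {
            "X2": chi["statistic"], "df": chi["df"], "p": chi["pvalue"]}
        print(f"chi-squared, tracking × estuary ({covariate}): "
              f"X² = {chi['statistic']:.2f}, df = {chi['df']}, "
              f"p = {chi['pvalue']:.4f}")

    # abundance trends vs tracking, chesapeake-like temperature model
    monitoring, _ = ingest.read_monitoring(
        ROOT / "data" / "chesapeake-like_monitoring.csv")
    trends = summaries.abundance_trends(monitoring)
    che = verdicts[(verdicts["estuary"] == "chesapeake-like")
                   & (verdicts["covariate"] == "temperature")]
    cross = summaries.crosstab_tracking_abundance(che, trends)
    report["tracking_vs_abundance"] = {
        "table": cross["table"].to_dict(),
        "test": None if cross["test"] is None else {
            "X2": cross["test"]["statistic"], "df": cross["test"]["df"],
            "p": cross["test"]["pvalue"]},
        "note": cross["note"]}
    print("\ntracking status × abundance trend (chesapeake-like, temperature):")
    print(cross["table"].to_string())

    (ROOT / "comparison_stats.json").write_text(
        json.dumps(report, indent=2, default=str) + "\n")


if __name__ == "__main__":
    main()
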