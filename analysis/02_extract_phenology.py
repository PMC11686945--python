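#!/usr/bin/env python
"""Validate and filter the monitoring tables, then extract yearly phenology.

Applies the ≥10-qualifying-year series filter, computes each series-year's
peak day-of-year (mid-month convention, circularly unwrapped) and attaches
annual and peak-season climate covariates.  Writes one phenology table per
estuary under results/.
"""

from pathlib import Path

from phenoshift import ingest, phenology

ROOT = Path(__file__).resolve().parents[1] / "results"
PRESETS = ("sanfrancisco-like", "chesapeake-like", "massbay-like")


def main() -> None:
    for name in PRESETS:
        monitoring, report = ingest.read_monitoring(
            ROOT / "data" / f"{name}_monitoring.csv")
        climate, _ = ingest.read_climate(ROOT / "data" / f"{name}_climate.csv")
        filtered, log = ingest.filter_series(monitoring)
        joined, match_rate = ingest.join_climate(filtered, climate)
        pheno = phenology.extract_phenology(filtered, climate)
        pheno.to_csv(ROOT / f"{name}_phenology.csv", index=False)
        unwrapped = (pheno["peak_doy_offset"] != 0).sum()
        print(f"{name}: {report.n_kept} valid rows, "
              f"{int(log['kept'].sum())}/{len(log)} series kept, "
              f"climate match {match_rate:.0%}, "
              f"{len(pheno)} series-years ({unwrapped} unwrapped peaks)")


if __name__ == "__main__":
    main()
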