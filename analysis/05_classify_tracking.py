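#!/usr/bin/env python
"""Classify each stratum as tracking or not tracking its local climate.

Applies the sign-consistency rule to the per-stratum slope triplets and
writes verdict and rate tables per estuary and covariate.
"""

from pathlib import Path

import pandas as pd

from phenoshift import tracking
from phenoshift.meta_model import SlopeEstimate, SlopeTriplet

ROOT = Path(__file__).resolve().parents[1] / "results"
PRESETS = ("sanfrancisco-like", "chesapeake-like", "massbay-like")


def triplets_from_table(df: pd.DataFrame) -> list[SlopeTriplet]:
    out = []
    for _, row in df.iterrows():
        comps = {}
        for etype in ("PT", "CT", "PC"):
            comps[etype] = SlopeEstimate(
                estimate=row[f"{etype}_estimate"], se=row[f"{etype}_se"],
                ci_low=row[f"{etype}_ci_low"], ci_high=row[f"{etype}_ci_high"])
        out.append(SlopeTriplet(group={"taxon": row["taxon"],
                                       "station": row["station"]},
                                PT=comps["PT"], CT=comps["CT"],
                                PC=comps["PC"]))
    return out


def main() -> None:
    for name in PRESETS:
        for covariate in ("temperature", "salinity"):
            slopes = triplets_from_table(
                pd.read_csv(ROOT / f"{name}_{covariate}_slopes.csv"))
            verdicts = [tracking.classify(s) for s in slopes]
            for v in verdicts:
                v.group["trophic_group"] = v.group["taxon"].rsplit("_", 1)[0]
            tracking.verdicts_table(verdicts).to_csv(
                ROOT / f"{name}_{covariate}_verdicts.csv", index=False)
            rates = tracking.tracking_rates(verdicts, by=("trophic_group",))
            rates.to_csv(ROOT / f"{name}_{covariate}_rates.csv", index=False)
            n_track = sum(v.tracking for v in verdicts)
            print(f"{name}/{covariate}: {n_track}/{len(verdicts)} strata "
                  "tracking")


if __name__ == "__main__":
    main()
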