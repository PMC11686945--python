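#!/usr/bin/env python
"""Confidence-ellipse diversity of (PT, CT) trends per trophic group.

Fits 95% ellipses (point estimate + Bayesian area draws) to each trophic
group's slope cloud per estuary and covariate, and computes pairwise
overlaps.  Writes ellipse summaries and an overlap table.
"""

from pathlib import Path
from itertools import combinations

import numpy as np
import pandas as pd

from phenoshift import trend_diversity as td

ROOT = Path(__file__).resolve().parents[1] / "results"
PRESETS = ("sanfrancisco-like", "chesapeake-like", "massbay-like")
SEED = 1


def main() -> None:
    summaries, overlaps = [], []
    for name in PRESETS:
        for covariate in ("temperature", "salinity"):
            df = pd.read_csv(ROOT / f"{name}_{covariate}_slopes.csv")
            df["trophic_group"] = df["taxon"].str.rsplit("_", n=1).str[0]
            ellipses = {}
            for g, grp in df.groupby("trophic_group"):
                pts = grp[["PT_estimate", "CT_estimate"]].to_numpy()
                try:
                    e = td.fit_ellipse(pts, n_draws=2000, seed=SEED, group=g)
                except td.DegenerateGeometryError:
                    continue
                ellipses[g] = e
                summaries.append({
                    "estuary": name, "covariate": covariate, "group": g,
                    "n_points": len(pts), "area_point": e.area_point,
                    "area_posterior_mean": e.area_posterior_mean,
                    "area_ci_low": e.area_credible[0],
                    "area_ci_high": e.area_credible[1]})
            for ga, gb in combinations(sorted(ellipses), 2):
                ov = td.ellipse_overlap(ellipses[ga], ellipses[gb],
                                        mc_points=100_000, seed=SEED)
                overlaps.append({
                    "estuary": name, "covariate": covariate,
                    "group_a": ga, "group_b": gb,
                    "overlap_of_union": ov.overlap_fraction,
                    "share_of_a": ov.share_a, "share_of_b": ov.share_b,
                    "mc_se": ov.mc_se})
    pd.DataFrame(summaries).to_csv(ROOT / "ellipse_summaries.csv", index=False)
    pd.DataFrame(overlaps).to_csv(ROOT / "ellipse_overlaps.csv", index=False)
    for row in overlaps:
        print(f"{row['estuary']}/{row['covariate']}: "
              f"{row['group_a']}–{row['group_b']} share "
              f"{100 * row['overlap_of_union']:.1f}% of ellipse space")


if __name__ == "__main__":
    main()
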