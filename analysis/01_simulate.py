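#!/usr/bin/env python
"""Generate the three synthetic estuaries and write their raw tables.

Each preset differs in which covariate trend dominates (salinity in the
San Francisco-like system, temperature in the Chesapeake- and Massachusetts
Bay-like systems).  Writes monitoring/climate CSVs plus the generative
ground truth under results/data/.
"""

from pathlib import Path

from phenoshift import ingest, synthetic

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(("sanfrancisco-like", "chesapeake-like",
                              "massbay-like")):
        cfg = synthetic.preset(name, seed=SEED + i)
        monitoring, climate, truth = synthetic.simulate(cfg)
        ingest.write_monitoring(monitoring, OUT / f"{name}_monitoring.csv")
        ingest.write_climate(climate, OUT / f"{name}_climate.csv")
        truth.taxa.to_csv(OUT / f"{name}_truth.csv", index=False)
        n_series = monitoring.groupby(["taxon", "station"]).ngroups
        print(f"{name}: {n_series} series × {cfg.years} years "
              f"({len(monitoring)} monthly rows), driver={cfg.driver}")


if __name__ == "__main__":
    main()
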