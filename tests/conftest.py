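import io

import numpy as np
import pandas as pd
import pytest

from phenoshift import synthetic


@pytest.fixture
def monitoring_csv() -> io.StringIO:
    """A tiny, well-formed monitoring CSV (3 rows)."""
    return io.StringIO(
        "estuary,region,station,taxon,trophic_group,year,month,value,value_kind\n"
        "bay,north,s1,copepod,zooplankton,2001,1,3.5,abundance\n"
        "bay,north,s1,copepod,zooplankton,2001,2,4.0,abundance\n"
        "bay,north,s1,copepod,zooplankton,2001,3,0.0,abundance\n"
    )


@pytest.fixture
def small_simulation():
    """One-taxon-per-group, one-station synthetic estuary (seeded)."""
    cfg = synthetic.preset("chesapeake-like", taxa_per_group=1,
                           regions_per_estuary=1, stations_per_region=1,
                           b_PT=-1.5, seed=11)
    monitoring, climate, truth = synthetic.simulate(cfg)
    return cfg, monitoring, climate, truth


def make_monitoring(rows: list[dict]) -> pd.DataFrame:
    base = {"estuary": "bay", "region": "north", "station": "s1",
            "taxon": "taxon_a", "trophic_group": "fish",
            "value_kind": "abundance"}
    return pd.DataFrame([{**base, **r} for r in rows])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
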