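"""Climate-tracking classification of slope triplets.

A stratum tracks its environment when the three slopes tell a congruent
story.  With significance judged by the 95% CI excluding zero:

* ``tracking_shift`` — PT, CT and PC all significant and the signs are
  consistent: sign(PT) = sign(PC) × sign(CT).  A taxon advancing its peak
  (PT < 0) in a warming system (CT > 0) must peak earlier when it is warmer
  (PC < 0).
* ``tracking_stationary`` — neither the phenology nor the climate is
  trending (PT and CT both non-significant): time does not decouple the
  taxon from its climate envelope.
* ``stationary_changing_climate`` — the climate trends but the phenology
  does not (PT non-significant, CT significant): the reporting bucket for
  taxa standing still in a moving environment.  Not tracking.
* ``not_tracking`` — everything else: shifts under a static climate, or a
  missing/inconsistent phenology–climate relationship.

Direction is taken from the phenological trend alone: ``advancing`` for a
significant negative PT slope, ``delaying`` for a significant positive one.
(A significant PT estimate of exactly zero — measure-zero in practice —
gets direction ``none``.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meta_model import SlopeTriplet

STATUSES = ("tracking_shift", "tracking_stationary",
            "stationary_changing_climate", "not_tracking")
TRACKING_STATUSES = frozenset({"tracking_shift", "tracking_stationary"})


@dataclass
class TrackingVerdict:
    group: dict
    status: str
    direction: str               # advancing / delaying / none
    inputs: dict                 # per effect type: (estimate, significant)

    @property
    def tracking(self) -> bool:
        return self.status in TRACKING_STATUSES


def classify(slopes: SlopeTriplet) -> TrackingVerdict:
    """Assign the tracking status and direction for one slope triplet."""
    comps = {}
    for etype in ("PT", "CT", "PC"):
        c = slopes.component(etype)
        if c.estimate is None or not np.isfinite(c.estimate):
            raise ValueError(f"{etype} estimate missing")
        comps[etype] = (float(c.estimate), bool(c.significant))

    (pt, pt_sig), (ct, ct_sig), (pc, pc_sig) = (comps["PT"], comps["CT"],
                                                comps["PC"])
    if pt_sig:
        consistent = (pc_sig and ct_sig
                      and np.sign(pt) == np.sign(pc) * np.sign(ct)
                      and np.sign(pt) != 0)
        status = "tracking_shift" if consistent else "not_tracking"
    elif ct_sig:
        status = "stationary_changing_climate"
    else:
        status = "tracking_stationary"

    if pt_sig and pt < 0:
        direction = "advancing"
    elif pt_sig and pt > 0:
        direction = "delaying"
    else:
        direction = "none"

    return TrackingVerdict(group=dict(slopes.group), status=status,
                           direction=direction,
                           inputs={k: v for k, v in comps.items()})


def verdicts_table(verdicts: list[TrackingVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        row = dict(v.group)
        row.update({"status": v.status, "direction": v.direction,
                    "tracking": v.tracking})
        for etype, (est, sig) in v.inputs.items():
            row[f"{etype}_estimate"] = est
            row[f"{etype}_significant"] = sig
        rows.append(row)
    return pd.DataFrame(rows)


def tracking_rates(verdicts: list[TrackingVerdict],
                   by: tuple[str, ...] = ()) -> pd.DataFrame:
    """Counts and proportions of each status (and direction) per group.

    ``by`` names keys of the verdicts' group dicts; empty groups simply do
    not appear (there is nothing to report for them).  Proportions sum to 1
    within each group.
    """
    df = verdicts_table(verdicts)
    if df.empty:
        return pd.DataFrame(columns=[*by, "status", "direction", "count",
                                     "proportion"])
    keys = list(by) if by else []
    if keys:
        missing = [k for k in keys if k not in df.columns]
        if missing:
            raise KeyError(f"grouping keys not present in verdicts: {missing}")
        grouped = df.groupby(keys)
    else:
        df["_all"] = "all"
        keys = ["_all"]
        grouped = df.groupby(keys)
    out = []
    for gkey, grp in grouped:
        gkey = gkey if isinstance(gkey, tuple) else (gkey,)
        total = len(grp)
        for (status, direction), sub in grp.groupby(["status", "direction"]):
            row = dict(zip(keys, gkey))
            row.update({"status": status, "direction": direction,
                        "count": len(sub), "proportion": len(sub) / total})
            out.append(row)
    res = pd.DataFrame(out)
    if "_all" in res.columns:
        res = res.drop(columns="_all")
    return res
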