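"""Correlation triplets, Fisher-z effect sizes, and their sampling covariance.

For each stratum (taxon × station × estuary × climate covariate × temporal
scale) three Pearson correlations are computed on a common set of years:

* ``PT`` — peak day-of-year vs. year (the phenological trend),
* ``CT`` — climate covariate vs. year (the local climate trend),
* ``PC`` — peak day-of-year vs. climate covariate (climate sensitivity).

Each correlation is Fisher-transformed, z = arctanh(r), with sampling
variance 1/(n−3).  The three effect sizes are *not* independent: every pair
shares one variable (PT and PC share phenology, PT and CT share time, PC and
CT share climate), which induces a sampling covariance.  For two
correlations r_ab and r_ac sharing variable a, the large-sample covariance
of their Fisher transforms is

    cov(z_ab, z_ac) =
        [ r_bc (1 − r_ab² − r_ac²) − ½ r_ab r_ac (1 − r_ab² − r_ac² − r_bc²) ]
        / [ (n − 3)(1 − r_ab²)(1 − r_ac²) ]

(the Olkin–Siotani / Steiger result for overlapping correlations).  The
within-stratum 3×3 covariance block assembled here feeds the block-diagonal
ε term of the trivariate meta-regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

R_CLAMP = 1.0 - 1e-12  # |r| clamp before arctanh

EFFECT_TYPES = ("PT", "CT", "PC")

# For each overlapping pair, which triplet entries play (r_ab, r_ac, r_bc):
# a is the shared variable, ab/ac the two correlations in the pair, bc the third.
_PAIR_ROLES = {
    frozenset({"PT", "PC"}): ("PT", "PC", "CT"),  # share phenology
    frozenset({"PT", "CT"}): ("PT", "CT", "PC"),  # share time
    frozenset({"PC", "CT"}): ("PC", "CT", "PT"),  # share climate
}


class StratumSkipped(Exception):
    """The stratum cannot yield a valid triplet (too few years or a
    zero-variance variable)."""


@dataclass
class CorrelationTriplet:
    """The three Pearson correlations of one stratum on a common year set."""

    p_PT: float
    p_CT: float
    p_PC: float
    n: int

    def __post_init__(self):
        if self.n < 4:
            raise ValueError(f"n={self.n} < 4; var = 1/(n-3) undefined")
        for name in ("p_PT", "p_CT", "p_PC"):
            r = getattr(self, name)
            if not np.isfinite(r) or abs(r) > 1:
                raise ValueError(f"{name}={r} is not a correlation")

    def r(self, which: str) -> float:
        return {"PT": self.p_PT, "CT": self.p_CT, "PC": self.p_PC}[which]


@dataclass
class EffectSizeTriplet:
    """Fisher-z triplet with its within-stratum covariance block."""

    z: np.ndarray            # (3,) in (PT, CT, PC) order
    Sigma: np.ndarray        # (3, 3)
    n: int
    triplet: CorrelationTriplet
    stratum: dict = field(default_factory=dict)

    @property
    def var(self) -> float:
        return sampling_variance(self.n)


def fisher_z(r) -> np.ndarray | float:
    """Fisher's variance-stabilizing transform, z = arctanh(r).

    Input is clamped to |r| <= 1 − 1e-12 so that perfect sample correlations
    map to a large finite z instead of infinity.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite correlation")
    out = np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))
    return float(out) if out.ndim == 0 else out


def sampling_variance(n: int) -> float:
    """Sampling variance of a Fisher-z correlation from n paired years."""
    if n <= 3:
        raise ValueError(f"n={n}: need at least 4 years for var = 1/(n-3)")
    return 1.0 / (n - 3)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise StratumSkipped("zero variance in a correlation input")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def pearson_triplet(years, peaks, covariate) -> CorrelationTriplet:
    """PT/CT/PC Pearson correlations on the common complete year set.

    Rows with a missing peak or covariate are dropped *jointly*, so that all
    three correlations use the same n — required for the shared 1/(n−3)
    sampling variance.
    """
    years = np.asarray(years, dtype=float)
    peaks = np.asarray(peaks, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    ok = np.isfinite(years) & np.isfinite(peaks) & np.isfinite(cov)
    years, peaks, cov = years[ok], peaks[ok], cov[ok]
    if len(years) < 4:
        raise StratumSkipped(f"only {len(years)} complete years (< 4)")
    return CorrelationTriplet(
        p_PT=_pearson(peaks, years),
        p_CT=_pearson(cov, years),
        p_PC=_pearson(peaks, cov),
        n=int(len(years)),
    )


def overlapping_cov(triplet: CorrelationTriplet, pair: tuple[str, str]) -> float:
    """Sampling covariance between two Fisher-z effect sizes of the triplet.

    ``pair`` names two of {"PT", "CT", "PC"}; the shared variable and the
    role of each correlation in the overlapping-correlations formula are
    resolved from the pair identity (see module docstring).
    """
    key = frozenset(pair)
    if key not in _PAIR_ROLES:
        raise ValueError(f"not an effect-size pair: {pair}")
    ab_name, ac_name, bc_name = _PAIR_ROLES[key]
    clamp = lambda r: float(np.clip(r, -R_CLAMP, R_CLAMP))
    r_ab, r_ac, r_bc = (clamp(triplet.r(ab_name)), clamp(triplet.r(ac_name)),
                        clamp(triplet.r(bc_name)))
    num = (r_bc * (1 - r_ab**2 - r_ac**2)
           - 0.5 * r_ab * r_ac * (1 - r_ab**2 - r_ac**2 - r_bc**2))
    den = (triplet.n - 3) * (1 - r_ab**2) * (1 - r_ac**2)
    return num / den


def build_block(triplet: CorrelationTriplet) -> np.ndarray:
    """Assemble the 3×3 within-stratum covariance block in (PT, CT, PC) order.

    The diagonal is the exact 1/(n−3); off-diagonals come from
    :func:`overlapping_cov`.  The large-sample off-diagonal formula can, for
    extreme correlations, produce a slightly indefinite matrix; in that case
    the off-diagonals are shrunk toward zero by the minimal common factor
    restoring positive semi-definiteness (the diagonal is never touched).
    """
    v = sampling_variance(triplet.n)
    block = np.full((3, 3), np.nan)
    np.fill_diagonal(block, v)
    for i, a in enumerate(EFFECT_TYPES):
        for j, b in enumerate(EFFECT_TYPES):
            if i < j:
                c = overlapping_cov(triplet, (a, b))
                block[i, j] = block[j, i] = c

    tol = -1e-10 * np.trace(block)
    if np.linalg.eigvalsh(block)[0] < tol:
        off = block - np.diag(np.diag(block))
        lo, hi = 0.0, 1.0
        for _ in range(60):  # bisect the shrink factor
            mid = 0.5 * (lo + hi)
            trial = np.diag(np.diag(block)) + mid * off
            if np.linalg.eigvalsh(trial)[0] >= tol:
                lo = mid
            else:
                hi = mid
        block = np.diag(np.diag(block)) + lo * off
    return block


def effect_size_triplet(triplet: CorrelationTriplet,
                        stratum: dict | None = None) -> EffectSizeTriplet:
    z = fisher_z(np.array([triplet.p_PT, triplet.p_CT, triplet.p_PC]))
    return EffectSizeTriplet(z=z, Sigma=build_block(triplet), n=triplet.n,
                             triplet=triplet, stratum=dict(stratum or {}))


def compute_effect_sizes(phenology: pd.DataFrame, covariate: str,
                         scale: str = "annual") -> list[EffectSizeTriplet]:
    """Effect-size triplets for every (taxon, station) stratum.

    Parameters
    ----------
    phenology : DataFrame
        Output of :func:`phenoshift.phenology.extract_phenology`.
    covariate : {"temperature", "salinity"}
    scale : {"annual", "seasonal"}
        Annual-mean covariate or the mean around the peak month.

    Strata with fewer than 4 complete years or a constant variable are
    skipped silently (they carry no trend information); the surviving
    triplets carry their stratum labels, year range, and covariance block.
    """
    col = {("temperature", "annual"): "annual_temp",
           ("salinity", "annual"): "annual_sal",
           ("temperature", "seasonal"): "seasonal_temp",
           ("salinity", "seasonal"): "seasonal_sal"}[(covariate, scale)]
    out = []
    for (taxon, station), grp in phenology.groupby(["taxon", "station"],
                                                   sort=True):
        grp = grp.sort_values("year")
        try:
            trip = pearson_triplet(grp["year"], grp["peak_doy"], grp[col])
        except StratumSkipped:
            continue
        ok = (np.isfinite(grp["peak_doy"]) & np.isfinite(grp[col]))
        years_used = grp.loc[ok, "year"]
        stratum = {
            "taxon": taxon, "station": station,
            "estuary": grp["estuary"].iloc[0],
            "region": grp["region"].iloc[0],
            "trophic_group": grp["trophic_group"].iloc[0],
            "covariate": covariate, "scale": scale,
            "start_year": int(years_used.min()),
            "end_year": int(years_used.max()),
        }
        out.append(effect_size_triplet(trip, stratum))
    return out


def effects_table(effects: list[EffectSizeTriplet]) -> pd.DataFrame:
    """Flatten triplets to one row per stratum (for CSV export)."""
    rows = []
    for e in effects:
        row = dict(e.stratum)
        row.update({
            "n": e.n,
            "r_PT": e.triplet.p_PT, "r_CT": e.triplet.p_CT,
            "r_PC": e.triplet.p_PC,
            "z_PT": e.z[0], "z_CT": e.z[1], "z_PC": e.z[2],
            "var": e.var,
            "cov_PT_CT": e.Sigma[0, 1], "cov_PT_PC": e.Sigma[0, 2],
            "cov_CT_PC": e.Sigma[1, 2],
        })
        rows.append(row)
    return pd.DataFrame(rows)
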