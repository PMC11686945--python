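"""Trivariate mixed-effects meta-regression on Fisher-z effect-size triplets.

The stacked model is

    z = W β + ε + u

where ``z`` holds the (z_PT, z_CT, z_PC) triplets of m strata (k = 3m), ``W``
is an effect-type design (each effect type, optionally crossed with
categorical moderators, gets its own column — intercept-free cell-means
coding), ``ε`` has the known block-diagonal within-stratum covariance V
assembled from the overlapping-correlation blocks, and ``u`` collects
between-population deviations: for each random grouping g (e.g. series start
year, series end year, station within region) every level carries a
3-dimensional deviation with covariance T_g, so

    Var(z) = Ω(θ) = V + Σ_g Z_g (I ⊗ T_g) Z_gᵀ .

Fitting maximizes the multivariate-normal likelihood over the variance
parameters θ (each T_g parameterized by its Cholesky factor, or its diagonal
only), with β profiled out by generalized least squares at every step.  The
primary output is the triplet of linearized slopes per moderator group with
Wald 95% confidence intervals; a slope is "significant" when its CI excludes
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .effect_sizes import EFFECT_TYPES, EffectSizeTriplet


class DesignError(ValueError):
    """The fixed-effect design cannot be built or is rank deficient."""


class UnderIdentifiedError(ValueError):
    """Fewer observations than fixed-effect parameters."""


@dataclass
class MetaDesign:
    """Stacked design for the trivariate meta-regression."""

    z: np.ndarray                      # (3m,)
    W: np.ndarray                      # (3m, p)
    V: np.ndarray                      # (m, 3, 3) within-stratum blocks
    columns: list[tuple[str, tuple]]   # (effect_type, moderator levels)
    groups: list[tuple]                # distinct moderator-level combos
    moderators: tuple[str, ...]
    strata: list[dict]
    random_groups: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.V.shape[0]

    @property
    def k(self) -> int:
        return self.z.size


@dataclass
class SlopeEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    significant: bool | None = None  # default: the CI-excludes-zero rule

    def __post_init__(self):
        if self.significant is None:
            self.significant = bool(self.ci_low > 0 or self.ci_high < 0)


@dataclass
class SlopeTriplet:
    group: dict
    PT: SlopeEstimate
    CT: SlopeEstimate
    PC: SlopeEstimate
    scale_of_estimate: str = "fisher_z"

    def component(self, which: str) -> SlopeEstimate:
        return {"PT": self.PT, "CT": self.CT, "PC": self.PC}[which]


@dataclass
class MetaFit:
    design: MetaDesign
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    tau2: dict[str, np.ndarray]        # grouping -> 3×3 T_g
    loglik: float
    converged: bool
    method: str = "ML"
    optimizer_message: str = ""

    def coefficients(self) -> pd.DataFrame:
        rows = []
        for (etype, combo), b, s in zip(self.design.columns, self.beta, self.se):
            rows.append({"effect_type": etype, "group": combo,
                         "estimate": b, "se": s})
        return pd.DataFrame(rows)


def build_design(effects: list[EffectSizeTriplet],
                 moderators: tuple[str, ...] | list[str] = (),
                 random: tuple[str, ...] | list[str] = ()) -> MetaDesign:
    """Stack effect-size triplets into the meta-regression design.

    Parameters
    ----------
    effects : list of EffectSizeTriplet
        One per stratum; stacked in (PT, CT, PC) order within stratum.
    moderators : sequence of stratum-attribute names
        Categorical moderators crossed with effect type (cell-means coding:
        each effect type × level combination has its own column, no global
        intercept).  Empty -> three effect-type intercept columns.
    random : sequence of stratum-attribute names
        Grouping factors for the between-population random effects.  A name
        of the form ``"inner:outer"`` nests the inner factor within the
        outer one (levels are (outer, inner) pairs).
    """
    if len(effects) < 1:
        raise DesignError("no strata")
    moderators = tuple(moderators)
    if len(set(moderators)) != len(moderators):
        raise DesignError(f"duplicate moderator columns: {moderators}")

    def combo_of(stratum: dict) -> tuple:
        vals = []
        for mname in moderators:
            if mname not in stratum or pd.isna(stratum[mname]):
                raise DesignError(
                    f"moderator {mname!r} unresolvable for stratum {stratum}")
            vals.append(stratum[mname])
        return tuple(vals)

    strata = [e.stratum for e in effects]
    combos = [combo_of(s) for s in strata]
    groups = sorted(set(combos))
    columns = [(etype, g) for g in groups for etype in EFFECT_TYPES]
    col_index = {c: i for i, c in enumerate(columns)}

    m = len(effects)
    z = np.concatenate([e.z for e in effects])
    V = np.stack([e.Sigma for e in effects])
    W = np.zeros((3 * m, len(columns)))
    for i, combo in enumerate(combos):
        for t, etype in enumerate(EFFECT_TYPES):
            W[3 * i + t, col_index[(etype, combo)]] = 1.0

    if 3 * m < W.shape[1]:
        raise UnderIdentifiedError(
            f"{3 * m} observations for {W.shape[1]} fixed-effect columns")
    if np.linalg.matrix_rank(W) < W.shape[1]:
        occupied = W.any(axis=0)
        empty = [columns[j] for j in np.flatnonzero(~occupied)]
        raise DesignError(f"design matrix is rank deficient "
                          f"(empty or collinear columns: {empty})")

    random_groups: dict[str, np.ndarray] = {}
    for rname in random:
        if ":" in rname:
            inner, outer = rname.split(":")
            labels = [(s.get(outer), s.get(inner)) for s in strata]
        else:
            labels = [s.get(rname) for s in strata]
        if any(lab is None or (isinstance(lab, tuple) and None in lab)
               for lab in labels):
            raise DesignError(f"random factor {rname!r} unresolvable")
        codes, _ = pd.factorize(np.array([str(lab) for lab in labels],
                                         dtype=object))
        random_groups[rname] = codes.astype(int)

    return MetaDesign(z=z, W=W, V=V, columns=columns, groups=groups,
                      moderators=moderators, strata=strata,
                      random_groups=random_groups)


# --- likelihood machinery -------------------------------------------------

def _theta_to_T(theta_g: np.ndarray, diagonal: bool) -> np.ndarray:
    """Map unconstrained parameters to a PSD 3×3 covariance T = L Lᵀ."""
    if diagonal:
        return np.diag(theta_g ** 2)
    L = np.zeros((3, 3))
    L[np.tril_indices(3)] = theta_g
    return L @ L.T


def _split_theta(theta: np.ndarray, names: list[str], diagonal: bool
                 ) -> dict[str, np.ndarray]:
    step = 3 if diagonal else 6
    return {name: _theta_to_T(theta[i * step:(i + 1) * step], diagonal)
            for i, name in enumerate(names)}


def _all_unique(codes: np.ndarray) -> bool:
    return len(np.unique(codes)) == len(codes)


def _profile_gls(design: MetaDesign, Ts: dict[str, np.ndarray],
                 reml: bool) -> tuple[float, np.ndarray, np.ndarray]:
    """Profiled log-likelihood and the GLS β, cov(β) at fixed T_g's.

    Uses a batched per-block path when Ω is block diagonal (every random
    grouping distinguishes every stratum), otherwise a dense factorization.
    """
    m, k, W, z = design.m, design.k, design.W, design.z
    p = W.shape[1]
    block_diagonal = all(_all_unique(codes)
                         for codes in design.random_groups.values())

    if block_diagonal:
        blocks = design.V.copy()
        for name in design.random_groups:
            blocks += Ts[name][None, :, :]
        try:
            L = np.linalg.cholesky(blocks)
        except np.linalg.LinAlgError:
            return -np.inf, np.full(p, np.nan), np.full((p, p), np.nan)
        logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
        Wb = W.reshape(m, 3, p)
        zb = z.reshape(m, 3)
        OiW = np.linalg.solve(blocks, Wb)
        Oiz = np.linalg.solve(blocks, zb[:, :, None])[:, :, 0]
        WtOiW = np.einsum("mip,miq->pq", Wb, OiW)
        WtOiz = np.einsum("mip,mi->p", Wb, Oiz)
        zOiz = float(np.einsum("mi,mi->", zb, Oiz))
    else:
        Omega = np.zeros((k, k))
        for i in range(m):
            Omega[3 * i:3 * i + 3, 3 * i:3 * i + 3] = design.V[i]
        for name, codes in design.random_groups.items():
            T = Ts[name]
            for level in np.unique(codes):
                idx = np.flatnonzero(codes == level)
                for a in idx:
                    for b in idx:
                        Omega[3 * a:3 * a + 3, 3 * b:3 * b + 3] += T
        try:
            c = np.linalg.cholesky(Omega)
        except np.linalg.LinAlgError:
            return -np.inf, np.full(p, np.nan), np.full((p, p), np.nan)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        OiW = np.linalg.solve(Omega, W)
        Oiz = np.linalg.solve(Omega, z)
        WtOiW = W.T @ OiW
        WtOiz = W.T @ Oiz
        zOiz = float(z @ Oiz)

    try:
        cov_beta = np.linalg.inv(WtOiW)
    except np.linalg.LinAlgError:
        return -np.inf, np.full(p, np.nan), np.full((p, p), np.nan)
    beta = cov_beta @ WtOiz
    quad = zOiz - float(beta @ WtOiz)
    ll = -0.5 * (k * np.log(2 * np.pi) + logdet + quad)
    if reml:
        sign, ld2 = np.linalg.slogdet(WtOiW)
        ll += 0.5 * (p * np.log(2 * np.pi) - ld2)
    return ll, beta, cov_beta


def fit_ml(design: MetaDesign, *, method: str = "ML",
           diagonal_random: bool = True, restarts: int = 5,
           seed: int = 0, tol: float = 1e-8) -> MetaFit:
    """Maximum-likelihood fit of the trivariate meta-regression.

    Variance components are estimated by bounded quasi-Newton optimization
    of the profiled likelihood, with ``restarts`` perturbed starting points;
    β and its covariance come from generalized least squares at the optimum.
    With no random groupings declared, the fit is plain GLS against the
    known within-stratum covariance (no optimization).

    ``diagonal_random=True`` (default) estimates only the per-effect-type
    variances of each T_g; set False to free the full 3×3 covariance via its
    Cholesky factor (needs enough strata per grouping to be identifiable).
    """
    if method not in ("ML", "REML"):
        raise ValueError(f"unknown method {method!r}")
    reml = method == "REML"
    names = list(design.random_groups)
    per = 3 if diagonal_random else 6

    if not names:
        ll, beta, cov_beta = _profile_gls(design, {}, reml)
        se = np.sqrt(np.diag(cov_beta))
        return MetaFit(design=design, beta=beta, se=se, cov_beta=cov_beta,
                       tau2={}, loglik=ll, converged=True, method=method)

    n_par = per * len(names)
    if design.m < 2:
        raise UnderIdentifiedError("random effects need at least 2 strata")

    def objective(theta):
        Ts = _split_theta(theta, names, diagonal_random)
        ll, _, _ = _profile_gls(design, Ts, reml)
        return np.inf if not np.isfinite(ll) else -ll

    # moment-flavoured start: spread of z around its GLS mean
    resid_scale = float(np.std(design.z)) or 0.1
    base = np.zeros(n_par)
    for i in range(len(names)):
        if diagonal_random:
            base[per * i:per * (i + 1)] = 0.5 * resid_scale
        else:
            block = np.zeros(6)
            block[[0, 2, 5]] = 0.5 * resid_scale  # diagonal of Cholesky
            base[per * i:per * (i + 1)] = block

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, restarts)):
        x0 = base if r == 0 else base * np.exp(rng.normal(0, 0.5, n_par))
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                options={"ftol": tol, "gtol": 1e-10,
                                         "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    Ts = _split_theta(best.x, names, diagonal_random)
    ll, beta, cov_beta = _profile_gls(design, Ts, reml)
    se = np.sqrt(np.diag(cov_beta))
    return MetaFit(design=design, beta=beta, se=se, cov_beta=cov_beta,
                   tau2=Ts, loglik=ll, converged=bool(best.success),
                   method=method, optimizer_message=str(best.message))


def wald_ci(fit: MetaFit, level: float = 0.95) -> pd.DataFrame:
    """Per-coefficient Wald confidence intervals and significance flags."""
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    q = stats.norm.ppf(0.5 + level / 2)
    df = fit.coefficients()
    df["ci_low"] = df["estimate"] - q * df["se"]
    df["ci_high"] = df["estimate"] + q * df["se"]
    df["significant"] = (df["ci_low"] > 0) | (df["ci_high"] < 0)
    return df


def extract_slopes(fit: MetaFit, *, back_transform: bool = False,
                   level: float = 0.95) -> list[SlopeTriplet]:
    """Per-group (PT, CT, PC) slope triplets with CIs.

    With cell-means coding every coefficient *is* its group's effect-type
    mean, so extraction is a re-indexing.  ``back_transform=True`` maps the
    estimates and CI endpoints through tanh to the correlation scale
    (monotone, so CI ordering and the significance verdict are preserved).
    """
    ci = wald_ci(fit, level)
    lookup = {(row["effect_type"], row["group"]): row
              for _, row in ci.iterrows()}
    out = []
    for g in fit.design.groups:
        comps = {}
        for etype in EFFECT_TYPES:
            row = lookup[(etype, g)]
            est, lo, hi = row["estimate"], row["ci_low"], row["ci_high"]
            if back_transform:
                est, lo, hi = np.tanh(est), np.tanh(lo), np.tanh(hi)
            comps[etype] = SlopeEstimate(estimate=float(est), se=float(row["se"]),
                                         ci_low=float(lo), ci_high=float(hi))
        group = dict(zip(fit.design.moderators, g))
        out.append(SlopeTriplet(
            group=group, PT=comps["PT"], CT=comps["CT"], PC=comps["PC"],
            scale_of_estimate="back_transformed_r" if back_transform
            else "fisher_z"))
    return out


def slopes_table(slopes: list[SlopeTriplet]) -> pd.DataFrame:
    rows = []
    for s in slopes:
        row = dict(s.group)
        for etype in EFFECT_TYPES:
            c = s.component(etype)
            row.update({f"{etype}_estimate": c.estimate, f"{etype}_se": c.se,
                        f"{etype}_ci_low": c.ci_low, f"{etype}_ci_high": c.ci_high,
                        f"{etype}_significant": c.significant})
        row["scale_of_estimate"] = s.scale_of_estimate
        rows.append(row)
    return pd.DataFrame(rows)
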