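"""Confidence-ellipse summaries of (PT, CT) trend diversity.

Each taxonomic group contributes a cloud of (PT, CT) slope pairs; the
diversity of trends within the group is summarized by a 95%-coverage
bivariate-normal ellipse.  With sample mean μ̂ and covariance Σ̂ the
point-estimate ellipse is { x : (x−μ̂)ᵀ Σ̂⁻¹ (x−μ̂) ≤ q } with
q = χ²₂(0.95) ≈ 5.991 and area π·q·√det(Σ̂).

Uncertainty in the area is propagated by conjugate Bayesian draws of the
covariance: a normal–inverse-Wishart posterior with a weakly informative
prior (df = d + 1 = 3, prior scale = the sample covariance) yields
posterior draws Σ ~ IW(ν₀ + n, Ψ₀ + S), each mapped to an area.

Overlap between two groups' ellipses is estimated by Monte Carlo over the
bounding box of the union and reported as intersection/union plus each
ellipse's shared share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class DegenerateGeometryError(ValueError):
    """Fewer than 3 points, or a collinear cloud: no 2-D ellipse exists."""


@dataclass
class EllipseSummary:
    group: str
    center: np.ndarray           # (2,)
    covariance: np.ndarray       # (2, 2) point-estimate covariance
    coverage: float
    area_point: float
    area_posterior_mean: float | None = None
    area_credible: tuple[float, float] | None = None
    draws_used: int = 0
    seed: int | None = None

    @property
    def chi2_quantile(self) -> float:
        return float(stats.chi2.ppf(self.coverage, df=2))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the coverage ellipse."""
        d = np.atleast_2d(points) - self.center
        sol = np.linalg.solve(self.covariance, d.T)
        md2 = np.einsum("ij,ji->i", d, sol)
        return md2 <= self.chi2_quantile

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned box enclosing the coverage ellipse."""
        half = np.sqrt(np.diag(self.covariance) * self.chi2_quantile)
        return self.center - half, self.center + half


@dataclass
class OverlapResult:
    groups: tuple[str, str]
    overlap_fraction: float      # intersection / union
    share_a: float               # intersection / area(a)
    share_b: float               # intersection / area(b)
    mc_points: int
    mc_se: float
    seed: int | None = None


def ellipse_area(covariance: np.ndarray, coverage: float = 0.95) -> float:
    """Area of the coverage ellipse of a bivariate normal: π·q·√det(Σ)."""
    q = stats.chi2.ppf(coverage, df=2)
    det = float(np.linalg.det(covariance))
    if det <= 0:
        raise DegenerateGeometryError("covariance is singular")
    return float(np.pi * q * np.sqrt(det))


def fit_ellipse(points, *, coverage: float = 0.95, n_draws: int = 4000,
                seed: int | None = 0, group: str = "",
                prior_df: int | None = None,
                prior_scale: np.ndarray | None = None) -> EllipseSummary:
    """Fit the 95% confidence ellipse to a cloud of (PT, CT) pairs.

    The point estimate uses the sample mean and covariance; Bayesian area
    uncertainty comes from inverse-Wishart posterior draws of the covariance
    under a weak conjugate prior (``prior_df`` defaults to d+1 = 3,
    ``prior_scale`` to the sample covariance).  Raises
    :class:`DegenerateGeometryError` for < 3 points or a collinear cloud.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (PT, CT) pairs")
    n = X.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"{n} points; need at least 3")
    center = X.mean(axis=0)
    S = (X - center).T @ (X - center)          # scatter matrix
    cov = S / (n - 1)
    if np.linalg.det(cov) <= 1e-300 * max(1.0, float(np.trace(cov)) ** 2):
        raise DegenerateGeometryError("points are collinear")
    area = ellipse_area(cov, coverage)

    nu0 = prior_df if prior_df is not None else 3          # d + 1
    Psi0 = prior_scale if prior_scale is not None else cov
    rng = np.random.default_rng(seed)
    if n_draws > 0:
        draws = stats.invwishart.rvs(df=nu0 + n, scale=Psi0 + S,
                                     size=n_draws, random_state=rng)
        areas = np.array([ellipse_area(d, coverage) for d in draws])
        post_mean = float(areas.mean())
        cred = (float(np.quantile(areas, 0.025)),
                float(np.quantile(areas, 0.975)))
    else:
        post_mean, cred = None, None
    return EllipseSummary(group=group, center=center, covariance=cov,
                          coverage=coverage, area_point=area,
                          area_posterior_mean=post_mean, area_credible=cred,
                          draws_used=max(n_draws, 0), seed=seed)


def ellipse_from_parameters(center, covariance, *, coverage: float = 0.95,
                            group: str = "") -> EllipseSummary:
    """Build a summary directly from a known mean and covariance."""
    cov = np.asarray(covariance, dtype=float)
    return EllipseSummary(group=group, center=np.asarray(center, dtype=float),
                          covariance=cov, coverage=coverage,
                          area_point=ellipse_area(cov, coverage))


def ellipse_overlap(a: EllipseSummary, b: EllipseSummary, *,
                    mc_points: int = 100_000,
                    seed: int | None = 0) -> OverlapResult:
    """Monte-Carlo overlap of two coverage ellipses.

    Uniform points are thrown over the bounding box of the union; the
    intersection/union fraction and each ellipse's shared share are
    estimated from inside-counts, with a binomial standard error on the
    union fraction.
    """
    for e in (a, b):
        if np.linalg.det(e.covariance) <= 0:
            raise DegenerateGeometryError(f"degenerate ellipse {e.group!r}")
    lo_a, hi_a = a.bounding_box()
    lo_b, hi_b = b.bounding_box()
    lo = np.minimum(lo_a, lo_b)
    hi = np.maximum(hi_a, hi_b)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(mc_points, 2))
    in_a = a.contains(pts)
    in_b = b.contains(pts)
    n_union = int((in_a | in_b).sum())
    n_inter = int((in_a & in_b).sum())
    if n_union == 0:
        raise DegenerateGeometryError("no point fell in either ellipse")
    frac = n_inter / n_union
    # binomial SE of the intersection share among union points
    se = float(np.sqrt(max(frac * (1 - frac), 1e-12) / n_union))
    share_a = n_inter / int(in_a.sum()) if in_a.any() else 0.0
    share_b = n_inter / int(in_b.sum()) if in_b.any() else 0.0
    return OverlapResult(groups=(a.group, b.group), overlap_fraction=frac,
                         share_a=share_a, share_b=share_b,
                         mc_points=mc_points, mc_se=se, seed=seed)
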