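"""Distribution theory for T-score vectors.

When the young-adult reference mean and SD at each site are estimated from a
finite sample of m young adults, a patient's T-score vector follows a
trivariate Student-t law (each marginal is a univariate t); as m grows the
law converges to the trivariate normal, which is the working model for the
simulation study.  This module provides the joint, marginal and conditional
densities of that family, the Mahalanobis distance that defines the
confidence ellipsoids, and the analytic coverage probabilities of the
ellipsoid-rule diagnostic categories.

Conventions
-----------
* Sites are indexed 0 (L1-L4 spine), 1 (femoral neck), 2 (total hip).
* ``rho12`` is the spine-neck correlation, ``rho13`` spine-hip,
  ``rho23`` neck-hip.
* ``dof = inf`` everywhere denotes the multivariate-normal limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, cholesky, eigh

from .reference import TScoreVector

__all__ = [
    "DegenerateModelError",
    "CorrelationModel",
    "TScoreDistribution",
    "mahalanobis2",
    "joint_pdf",
    "marginal_distribution",
    "conditional_distribution",
    "category_coverage",
    "who_category_probabilities",
    "orthant_band_probability",
]


class DegenerateModelError(ValueError):
    """Raised when a correlation/scale matrix is not positive definite."""


@dataclass(frozen=True)
class CorrelationModel:
    """3x3 positive-definite correlation matrix of the three T-scores.

    Parameters are the three pairwise correlations; the implied matrix has a
    unit diagonal.  Positive definiteness is validated at construction.
    """

    rho12: float
    rho13: float
    rho23: float

    def __post_init__(self) -> None:
        for name in ("rho12", "rho13", "rho23"):
            r = getattr(self, name)
            if not (-1.0 < r < 1.0):
                raise DegenerateModelError(f"{name}={r} outside (-1, 1)")
        if np.linalg.eigvalsh(self.matrix).min() <= 0:
            raise DegenerateModelError(
                f"correlation matrix for ({self.rho12}, {self.rho13}, {self.rho23}) "
                "is not positive definite"
            )

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [1.0, self.rho12, self.rho13],
                [self.rho12, 1.0, self.rho23],
                [self.rho13, self.rho23, 1.0],
            ]
        )

    @classmethod
    def equicorrelation(cls, rho: float) -> "CorrelationModel":
        """All three pairwise correlations equal: R = (1-rho) I + rho J."""
        return cls(rho, rho, rho)

    @classmethod
    def from_matrix(cls, R: np.ndarray) -> "CorrelationModel":
        R = np.asarray(R, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R, R.T):
            raise DegenerateModelError("expected a symmetric 3x3 matrix")
        if not np.allclose(np.diag(R), 1.0):
            raise DegenerateModelError("correlation matrix must have unit diagonal")
        return cls(R[0, 1], R[0, 2], R[1, 2])

    def sqrt(self, method: str = "symmetric_sqrt") -> np.ndarray:
        """A square root S with S S^T = R.

        ``symmetric_sqrt`` is the eigendecomposition (principal) root — the
        unique symmetric PD root; ``cholesky`` is the lower-triangular root.
        """
        R = self.matrix
        if method == "symmetric_sqrt":
            w, v = eigh(R)
            if w.min() <= 0:
                raise DegenerateModelError("matrix not positive definite")
            return (v * np.sqrt(w)) @ v.T
        if method == "cholesky":
            return cholesky(R, lower=True)
        raise ValueError(f"unknown square-root method {method!r}")


def _as_vector(t) -> np.ndarray:
    if isinstance(t, TScoreVector):
        return t.as_array()
    arr = np.asarray(t, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected 3 T-score components, got shape {arr.shape}")
    return arr


def mahalanobis2(t, model: CorrelationModel, center: Sequence[float] = (0.0, 0.0, 0.0)) -> float | np.ndarray:
    """Squared Mahalanobis distance d^2 = (t-c)^T R^{-1} (t-c).

    Accepts a single :class:`TScoreVector` / length-3 array or an (n, 3)
    array of rows; returns a scalar or length-n array accordingly.
    """
    x = _as_vector(t) - np.asarray(center, dtype=float)
    try:
        c = cho_factor(model.matrix)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in ctor
        raise DegenerateModelError("singular correlation matrix") from exc
    if x.ndim == 1:
        return float(x @ cho_solve(c, x))
    return np.einsum("ij,ij->i", x, cho_solve(c, x.T).T)


@dataclass(frozen=True)
class TScoreDistribution:
    """Joint law of the T-score vector.

    With a finite young-adult reference sample of size ``reference_n = m``
    per site, (X - Xbar)/S at each site is a scaled Student-t, and jointly
    the T-score vector is modelled as trivariate t with

        dof   = m - 1,
        scale = ((m + 1) / m) * R,

    centered at the young-adult reference point (T = 0 by default).  With
    ``reference_n = inf`` (the default) the reference is exact and the law
    is trivariate normal with covariance R.
    """

    model: CorrelationModel
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    reference_n: float = math.inf

    def __post_init__(self) -> None:
        m = self.reference_n
        if math.isfinite(m) and m < 3:
            raise ValueError("finite reference sample size must be >= 3 (dof > 1)")

    @property
    def dof(self) -> float:
        return math.inf if math.isinf(self.reference_n) else self.reference_n - 1.0

    @property
    def scale(self) -> np.ndarray:
        m = self.reference_n
        factor = 1.0 if math.isinf(m) else (m + 1.0) / m
        return factor * self.model.matrix


def joint_pdf(t, dist: TScoreDistribution) -> float | np.ndarray:
    """Joint density of the T-score vector (trivariate t, or normal limit)."""
    x = _as_vector(t)
    mu = np.asarray(dist.center, dtype=float)
    if math.isinf(dist.dof):
        return stats.multivariate_normal(mean=mu, cov=dist.scale).pdf(x)
    if dist.dof <= 0:
        raise ValueError(f"degrees of freedom must be positive, got {dist.dof}")
    return stats.multivariate_t(loc=mu, shape=dist.scale, df=dist.dof).pdf(x)


def marginal_distribution(dist: TScoreDistribution, site_index: int):
    """Marginal law of one T-score: univariate t (or normal), frozen scipy dist.

    ``site_index`` is 0 (spine), 1 (femoral neck) or 2 (total hip).
    """
    if site_index not in (0, 1, 2):
        raise IndexError(f"site_index must be 0, 1 or 2, got {site_index}")
    loc = dist.center[site_index]
    s = math.sqrt(dist.scale[site_index, site_index])
    if math.isinf(dist.dof):
        return stats.norm(loc=loc, scale=s)
    return stats.t(df=dist.dof, loc=loc, scale=s)


def conditional_distribution(dist: TScoreDistribution, target_site: int, observed: Sequence[float]):
    """Law of one T-score given the other two, as a frozen scipy distribution.

    For the trivariate t with dof nu, conditioning on the 2-vector x2 gives a
    univariate t with

        dof      nu + 2
        location mu_1 + S12 S22^{-1} (x2 - mu_2)
        scale^2  ((nu + d2) / (nu + 2)) * (S11 - S12 S22^{-1} S21)

    where d2 is the Mahalanobis distance of x2 under (mu_2, S22).  The
    normal-theory conditional (no scale inflation) is returned when dof=inf.

    Parameters
    ----------
    target_site
        Index (0..2) of the unobserved site.
    observed
        The two known T-scores, in increasing site-index order of the
        remaining sites.
    """
    if target_site not in (0, 1, 2):
        raise IndexError(f"target_site must be 0, 1 or 2, got {target_site}")
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (2,) or not np.all(np.isfinite(obs)):
        raise ValueError("observed must be the two finite T-scores of the other sites")

    others = [i for i in range(3) if i != target_site]
    S = dist.scale
    mu = np.asarray(dist.center, dtype=float)
    S11 = S[target_site, target_site]
    S12 = S[target_site, others]
    S22 = S[np.ix_(others, others)]
    try:
        c22 = cho_factor(S22)
    except np.linalg.LinAlgError as exc:
        raise DegenerateModelError("observed-block scale is degenerate") from exc
    w = cho_solve(c22, obs - mu[others])
    loc = mu[target_site] + S12 @ w
    var = S11 - S12 @ cho_solve(c22, S12)
    if var <= 0:
        raise DegenerateModelError("conditional variance is not positive")

    if math.isinf(dist.dof):
        return stats.norm(loc=loc, scale=math.sqrt(var))
    d2 = float((obs - mu[others]) @ w)
    infl = (dist.dof + d2) / (dist.dof + 2.0)
    return stats.t(df=dist.dof + 2.0, loc=loc, scale=math.sqrt(infl * var))


def category_coverage(
    model: CorrelationModel | None = None,
    dof: float = math.inf,
    radii: tuple[float, float] = (1.0, 2.5),
) -> tuple[float, float, float]:
    """Analytic category probabilities of the ellipsoid rule at the origin.

    Under the zero-centered elliptical law, d^2 follows chi2_3 (dof=inf) or
    3 * F(3, dof) (finite dof), independently of the correlation entries;
    exactly half of the mass at any radius lies on the low-BMD side of the
    T-score-sum hyperplane.  Hence

        P(osteoporosis) = (1/2) P(d >= r_op)
        P(osteopenia)   = (1/2) [P(d > r_pen) - P(d >= r_op)]
        P(normal)       = the rest.

    Returns ``(p_osteoporosis, p_osteopenia, p_normal)``, summing to 1.
    The ``model`` argument is accepted for interface symmetry; the result
    does not depend on it.
    """
    r_pen, r_op = radii
    if not (0 < r_pen < r_op):
        raise ValueError(f"radii must satisfy 0 < r_pen < r_op, got {radii}")
    if math.isinf(dof):
        tail = lambda q: stats.chi2.sf(q, df=3)
    else:
        if dof <= 0:
            raise ValueError(f"degrees of freedom must be positive, got {dof}")
        tail = lambda q: stats.f.sf(q / 3.0, 3, dof)
    p_op = 0.5 * tail(r_op**2)
    p_pen = 0.5 * (tail(r_pen**2) - tail(r_op**2))
    return p_op, p_pen, 1.0 - p_op - p_pen


# --- analytic WHO-rule probabilities (normal model), used as cross-checks ---

def orthant_band_probability(
    model: CorrelationModel,
    lower: float | Sequence[float],
    upper: float | Sequence[float],
) -> float:
    """P(lower_i < X_i < upper_i for all i) for zero-mean normal X ~ N(0, R)."""
    lo = np.broadcast_to(np.asarray(lower, dtype=float), (3,))
    hi = np.broadcast_to(np.asarray(upper, dtype=float), (3,))
    d = stats.multivariate_normal(mean=np.zeros(3), cov=model.matrix)
    return float(d.cdf(hi, lower_limit=lo))


def who_category_probabilities(model: CorrelationModel) -> tuple[float, float, float]:
    """Analytic (p_osteoporosis, p_osteopenia, p_normal) under the WHO rule
    for a zero-mean, unit-variance trivariate normal T-score vector.

    p_normal = P(min T > -1), p_osteoporosis = P(min T <= -2.5), computed by
    numerical integration of the trivariate normal orthant probabilities.
    """
    p_norm = orthant_band_probability(model, -1.0, math.inf)
    p_op = 1.0 - orthant_band_probability(model, -2.5, math.inf)
    return p_op, 1.0 - p_norm - p_op, p_norm
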