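"""Synthetic cohort generation.

Two generators:

* :func:`simulate_cohort` — trivariate normal T-score vectors with a
  configurable correlation structure.  The simulation study draws 1000
  postmenopausal women per column at equicorrelation 0, 0.2, 0.4, 0.6, 0.8,
  with the simulated elderly population set equal to the young-adult
  reference (marginally standard-normal T-scores); this identification is
  what makes the WHO-normal rate at zero correlation equal Phi(1)^3.
* :func:`emulate_real_cohort` — a cohort shaped like the real screening
  population of 1000 65-year-old women: site-specific T-score means
  (-0.90, -1.54, -0.97), SDs (1.50, 0.93, 1.04) and inter-site BMD
  correlations (0.6558, 0.6145, 0.7508), plus optional Bernoulli clinical
  covariates (diabetes 7.1%, prior fracture 2.4%, supplementation 60.3%).

The default correlating transform is the symmetric (principal) matrix square
root.  Combined with common random numbers it makes each row's Mahalanobis
distance — and the sign of its T-score sum — identical across equicorrelation
levels, so the ellipsoid-rule counts are bit-for-bit invariant along the
correlation grid while the WHO counts move.  Cholesky is available for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import T_COLUMNS
from .mvt import CorrelationModel

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "draw_standard_normals",
    "emulate_real_cohort",
    "REAL_COHORT_MEANS",
    "REAL_COHORT_SDS",
    "REAL_COHORT_CORR",
]

#: Real-cohort T-score means (spine, femoral neck, total hip).
REAL_COHORT_MEANS = (-0.90, -1.54, -0.97)
#: Real-cohort T-score SDs.
REAL_COHORT_SDS = (1.50, 0.93, 1.04)
#: Real-cohort inter-site correlations (rho12, rho13, rho23).
REAL_COHORT_CORR = (0.6558, 0.6145, 0.7508)

_COVARIATE_RATES = {"diabetes": 0.071, "prior_fx": 0.024, "supplement": 0.603}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated cohort.

    ``rho`` may be a single equicorrelation or the full
    ``(rho12, rho13, rho23)`` triple.  ``means``/``sds`` are per-site on the
    T-score scale; the defaults (0, 1) generate marginally standard-normal
    T-scores, i.e. an elderly population indistinguishable from the
    young-adult reference.
    """

    n: int = 1000
    rho: float | tuple[float, float, float] = 0.0
    means: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sds: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    transform: str = "symmetric_sqrt"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("per-site SDs must be positive")
        if self.transform not in ("symmetric_sqrt", "cholesky"):
            raise ValueError(f"unknown transform {self.transform!r}")
        self.model  # validates positive definiteness

    @property
    def model(self) -> CorrelationModel:
        if np.isscalar(self.rho):
            return CorrelationModel.equicorrelation(float(self.rho))
        return CorrelationModel(*self.rho)


def draw_standard_normals(n: int, seed: int) -> np.ndarray:
    """(n, 3) iid standard normals — the common-random-number base draw."""
    return np.random.default_rng(seed).standard_normal((n, 3))


def simulate_cohort(config: SimulationConfig, z: np.ndarray | None = None) -> pd.DataFrame:
    """Generate a cohort table of correlated T-score triples.

    Each row is ``means + sds * (S z)`` with ``S`` the chosen square root of
    the correlation matrix and ``z`` iid standard normal.  Pass a pre-drawn
    ``z`` (from :func:`draw_standard_normals`) to reuse common random numbers
    across correlation structures; by default it is drawn from
    ``config.seed``.  Fixed seed implies bit-identical output.
    """
    if z is None:
        z = draw_standard_normals(config.n, config.seed)
    z = np.asarray(z, dtype=float)
    if z.shape != (config.n, 3):
        raise ValueError(f"z must have shape ({config.n}, 3), got {z.shape}")
    S = config.model.sqrt(config.transform)
    t = np.asarray(config.means) + np.asarray(config.sds) * (z @ S.T)
    table = pd.DataFrame(t, columns=list(T_COLUMNS))
    table.insert(0, "patient_id", np.arange(1, config.n + 1))
    return table


def emulate_real_cohort(
    seed: int,
    n: int = 1000,
    covariates: bool = False,
    transform: str = "symmetric_sqrt",
) -> pd.DataFrame:
    """A synthetic stand-in for the real 1000-woman screening cohort.

    T-scores are trivariate normal with the real cohort's published means,
    SDs and inter-site correlations; clinical covariates, when requested,
    are independent Bernoulli draws at the published prevalences.  The
    result emulates the cohort's first and second moments only — it carries
    none of the skewness, machine mix or covariate-BMD dependence of the
    actual patient data.
    """
    config = SimulationConfig(
        n=n,
        rho=REAL_COHORT_CORR,
        means=REAL_COHORT_MEANS,
        sds=REAL_COHORT_SDS,
        seed=seed,
        transform=transform,
    )
    table = simulate_cohort(config)
    if covariates:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
        for name, rate in _COVARIATE_RATES.items():
            table[name] = (rng.random(n) < rate).astype(int)
    return table
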