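"""Diagnostic rules: univariate WHO/ISCD and the multivariate ellipsoid rule.

WHO/ISCD rule (lowest T-score):
    osteoporosis  iff  min(T) <= -2.5
    osteopenia    iff  -2.5 < min(T) < -1      (both inequalities strict)
    normal        otherwise

Ellipsoid rule: with d the Mahalanobis distance of the T-score triple from
the young-adult origin under the inter-site correlation model, and
s = t_spine + t_neck + t_hip the low-BMD direction gate,
    osteoporosis  iff  d >= 2.5 and s < 0
    osteopenia    iff  1 < d < 2.5 and s < 0
    normal        otherwise.
The boundary conventions mirror the WHO inequalities (osteoporosis
inclusive, osteopenia strict at both radii); the gate keeps high-BMD
outliers — outside the ellipsoid but with above-reference bone density —
out of the disease categories.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mvt import CorrelationModel, mahalanobis2
from .reference import TScoreVector

__all__ = [
    "Diagnosis",
    "CongruenceResult",
    "who_classify",
    "site_classify",
    "congruence",
    "ellipsoid_classify",
    "classify_cohort",
    "annotate_cohort",
    "T_COLUMNS",
]

#: Cohort-table column names for the three T-scores, in canonical site order.
T_COLUMNS = ("t_l1l4", "t_fneck", "t_thip")

#: Default (osteopenia, osteoporosis) Mahalanobis boundary radii — the
#: magnitudes of the univariate WHO thresholds.
DEFAULT_RADII = (1.0, 2.5)


class Diagnosis(enum.IntEnum):
    """Ordered diagnostic category: normal < osteopenia < osteoporosis."""

    NORMAL = 0
    OSTEOPENIA = 1
    OSTEOPOROSIS = 2

    def __str__(self) -> str:  # CSV-friendly
        return self.name.lower()


def site_classify(t_single: float) -> Diagnosis:
    """WHO thresholds applied to a single site's T-score."""
    if t_single <= -2.5:
        return Diagnosis.OSTEOPOROSIS
    if t_single < -1.0:
        return Diagnosis.OSTEOPENIA
    return Diagnosis.NORMAL


def who_classify(t: TScoreVector) -> Diagnosis:
    """WHO/ISCD diagnosis from the lowest of the three T-scores."""
    return site_classify(min(_components(t)))


@dataclass(frozen=True)
class CongruenceResult:
    """Per-site WHO diagnoses and whether all three agree."""

    per_site: tuple[Diagnosis, Diagnosis, Diagnosis]
    congruent: bool
    congruent_category: Diagnosis | None

    def __post_init__(self) -> None:
        assert self.congruent == (self.congruent_category is not None)


def congruence(t: TScoreVector) -> CongruenceResult:
    """Do the three sites individually yield the same WHO diagnosis?"""
    per_site = tuple(site_classify(x) for x in _components(t))
    agree = per_site[0] == per_site[1] == per_site[2]
    return CongruenceResult(per_site, agree, per_site[0] if agree else None)


def ellipsoid_classify(
    t: TScoreVector,
    model: CorrelationModel,
    radii: tuple[float, float] = DEFAULT_RADII,
) -> Diagnosis:
    """Multivariate diagnosis from the Mahalanobis ellipsoids.

    ``radii`` is ``(r_osteopenia, r_osteoporosis)``; severity requires both
    sufficient Mahalanobis radius and a negative T-score sum (net bone
    deficit relative to the young-adult reference).
    """
    r_pen, r_op = _check_radii(radii)
    x = _components(t)
    d = float(np.sqrt(mahalanobis2(x, model)))
    if x.sum() >= 0:
        return Diagnosis.NORMAL
    if d >= r_op:
        return Diagnosis.OSTEOPOROSIS
    if d > r_pen:
        return Diagnosis.OSTEOPENIA
    return Diagnosis.NORMAL


def classify_cohort(
    cohort: pd.DataFrame,
    rule: str,
    model: CorrelationModel | None = None,
    radii: tuple[float, float] = DEFAULT_RADII,
) -> tuple[pd.Series, dict[Diagnosis, int]]:
    """Classify every row of a cohort table by one rule.

    Parameters
    ----------
    cohort
        Table with the T-score columns ``t_l1l4, t_fneck, t_thip``.
    rule
        ``"who"`` or ``"ellipsoid"``.
    model
        Required for the ellipsoid rule.

    Returns
    -------
    (per_row, counts)
        ``per_row`` is a :class:`pandas.Series` of :class:`Diagnosis` aligned
        with the cohort index; ``counts`` maps every category (including
        empty ones) to its count, summing to ``len(cohort)``.
    """
    x = _cohort_matrix(cohort)
    if rule == "who":
        codes = _who_codes(x)
    elif rule == "ellipsoid":
        if model is None:
            raise ValueError("the ellipsoid rule requires a correlation model")
        codes = _ellipsoid_codes(x, model, radii)
    else:
        raise ValueError(f"unknown rule {rule!r}; expected 'who' or 'ellipsoid'")
    # dtype=object keeps Diagnosis members (IntEnum would decay to int64)
    per_row = pd.Series([Diagnosis(c) for c in codes], index=cohort.index,
                        name=f"{rule}_dx", dtype=object)
    counts = Counter(per_row)
    return per_row, {d: counts.get(d, 0) for d in Diagnosis}


def annotate_cohort(
    cohort: pd.DataFrame,
    model: CorrelationModel,
    radii: tuple[float, float] = DEFAULT_RADII,
) -> pd.DataFrame:
    """Input columns plus ``who_dx``, ``ellipsoid_dx``, ``d2``, ``congruent``."""
    x = _cohort_matrix(cohort)
    out = cohort.copy()
    out["who_dx"] = [str(Diagnosis(c)) for c in _who_codes(x)]
    out["ellipsoid_dx"] = [str(Diagnosis(c)) for c in _ellipsoid_codes(x, model, radii)]
    out["d2"] = mahalanobis2(x, model) if len(x) else np.zeros(0)
    site_codes = _site_codes(x)
    out["congruent"] = (site_codes == site_codes[:, [0]]).all(axis=1) if len(x) else np.zeros(0, bool)
    return out


# --- vectorized internals -------------------------------------------------

def _components(t) -> np.ndarray:
    if isinstance(t, TScoreVector):
        return t.as_array()
    arr = np.asarray(t, dtype=float)
    if arr.shape != (3,):
        raise ValueError("expected a complete triple of T-scores")
    if not np.all(np.isfinite(arr)):
        raise ValueError("T-scores must all be finite")
    return arr


def _check_radii(radii) -> tuple[float, float]:
    r_pen, r_op = radii
    if not (0 < r_pen < r_op):
        raise ValueError(f"radii must satisfy 0 < r_pen < r_op, got {radii}")
    return float(r_pen), float(r_op)


def _cohort_matrix(cohort: pd.DataFrame) -> np.ndarray:
    missing = [c for c in T_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing T-score column(s) {missing}")
    return cohort.loc[:, list(T_COLUMNS)].to_numpy(dtype=float)


def _site_codes(x: np.ndarray) -> np.ndarray:
    codes = np.zeros(x.shape, dtype=int)
    codes[x < -1.0] = int(Diagnosis.OSTEOPENIA)
    codes[x <= -2.5] = int(Diagnosis.OSTEOPOROSIS)
    return codes


def _who_codes(x: np.ndarray) -> np.ndarray:
    if len(x) == 0:
        return np.zeros(0, dtype=int)
    return _site_codes(x).max(axis=1)


def _ellipsoid_codes(x: np.ndarray, model: CorrelationModel, radii) -> np.ndarray:
    r_pen, r_op = _check_radii(radii)
    if len(x) == 0:
        return np.zeros(0, dtype=int)
    d2 = mahalanobis2(x, model)
    low = x.sum(axis=1) < 0
    codes = np.zeros(len(x), dtype=int)
    codes[low & (d2 > r_pen**2)] = int(Diagnosis.OSTEOPENIA)
    codes[low & (d2 >= r_op**2)] = int(Diagnosis.OSTEOPOROSIS)
    return codes
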