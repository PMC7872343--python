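"""The comparative experiments: correlation-grid simulation study, paired
rule comparison (McNemar), and FRAX group comparison.

``run_table3`` reproduces the simulation-study grid: for each equicorrelation
level it simulates a cohort (common random numbers across the grid), applies
both diagnostic rules against the matching correlation model, and tabulates
per-site congruence and the two rules' category counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    Diagnosis,
    T_COLUMNS,
    classify_cohort,
)
from .mvt import CorrelationModel
from .simulate import SimulationConfig, draw_standard_normals, simulate_cohort

__all__ = [
    "Table3Column",
    "Table3Report",
    "run_table3",
    "McNemarResult",
    "mcnemar",
    "RuleComparison",
    "compare_rules",
    "frax_group_compare",
]

_CATS = (Diagnosis.OSTEOPOROSIS, Diagnosis.OSTEOPENIA, Diagnosis.NORMAL)


@dataclass(frozen=True)
class Table3Column:
    """One correlation level of the simulation-study grid."""

    rho: float
    congruent: dict[Diagnosis, int]  # rows where all 3 sites agree, by category
    who: dict[Diagnosis, int]
    ellipsoid: dict[Diagnosis, int]

    def __post_init__(self) -> None:
        n_who = sum(self.who.values())
        assert sum(self.ellipsoid.values()) == n_who


@dataclass(frozen=True)
class Table3Report:
    n: int
    seed: int
    transform: str
    columns: tuple[Table3Column, ...]

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per (rho, statistic)."""
        rows = {}
        for col in self.columns:
            c = {}
            for cat in _CATS:
                c[f"congruent_{cat}"] = col.congruent[cat]
                c[f"who_{cat}"] = col.who[cat]
                c[f"ellipsoid_{cat}"] = col.ellipsoid[cat]
            rows[col.rho] = c
        frame = pd.DataFrame(rows)
        frame.columns.name = "rho"
        return frame

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        pct = frame / self.n * 100.0
        out = frame.astype(str) + " (" + pct.map(lambda p: f"{p:.1f}") + "%)"
        out.index.name = "statistic"
        out.to_csv(path, sep="\t")


def run_table3(
    n: int = 1000,
    rho_grid: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8),
    seed: int = 0,
    transform: str = "symmetric_sqrt",
    radii: tuple[float, float] = (1.0, 2.5),
) -> Table3Report:
    """Run the correlation-grid simulation study.

    A single (n, 3) standard-normal draw is shared by every grid column
    (common random numbers), so differences between columns reflect the
    correlation structure alone.  With the default symmetric-square-root
    transform the ellipsoid-rule counts are identical in every column.
    """
    z = draw_standard_normals(n, seed)
    columns = []
    for rho in rho_grid:
        config = SimulationConfig(n=n, rho=rho, seed=seed, transform=transform)
        cohort = simulate_cohort(config, z=z)
        model = config.model
        who_rows, who_counts = classify_cohort(cohort, "who")
        _, ell_counts = classify_cohort(cohort, "ellipsoid", model=model, radii=radii)
        x = cohort.loc[:, list(T_COLUMNS)].to_numpy()
        site = np.zeros(x.shape, dtype=int)
        site[x < -1.0] = 1
        site[x <= -2.5] = 2
        agree = (site == site[:, [0]]).all(axis=1)
        congruent = {
            cat: int(np.sum(agree & (site[:, 0] == int(cat)))) for cat in Diagnosis
        }
        columns.append(Table3Column(rho=rho, congruent=congruent, who=who_counts, ellipsoid=ell_counts))
    return Table3Report(n=n, seed=seed, transform=transform, columns=tuple(columns))


@dataclass(frozen=True)
class McNemarResult:
    b: int  # discordant: rule A positive only
    c: int  # discordant: rule B positive only
    chi2: float
    p: float


def mcnemar(b: int, c: int) -> McNemarResult:
    """McNemar's test on the discordant pair counts, without continuity
    correction: chi2 = (b - c)^2 / (b + c) against chi2 with 1 dof."""
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        raise ValueError("McNemar's test is undefined with no discordant pairs")
    chi2 = (b - c) ** 2 / (b + c)
    return McNemarResult(b=b, c=c, chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)))


@dataclass(frozen=True)
class RuleComparison:
    """Paired comparison of the WHO and ellipsoid rules on one cohort."""

    crosstab: pd.DataFrame  # 3x3, rows = WHO category, columns = ellipsoid
    osteoporosis: McNemarResult  # osteoporosis vs not
    disease: McNemarResult  # osteopenia-or-worse vs normal
    who_counts: dict[Diagnosis, int]
    ellipsoid_counts: dict[Diagnosis, int]


def compare_rules(
    cohort: pd.DataFrame,
    model: CorrelationModel,
    radii: tuple[float, float] = (1.0, 2.5),
) -> RuleComparison:
    """3x3 paired cross-tabulation of the two rules plus McNemar tests for
    the two dichotomizations (osteoporosis vs not; any disease vs normal)."""
    who_rows, who_counts = classify_cohort(cohort, "who")
    ell_rows, ell_counts = classify_cohort(cohort, "ellipsoid", model=model, radii=radii)
    labels = [str(d) for d in Diagnosis]
    tab = pd.crosstab(
        who_rows.map(str), ell_rows.map(str), rownames=["who"], colnames=["ellipsoid"]
    ).reindex(index=labels, columns=labels, fill_value=0)

    def discordant(positive) -> McNemarResult:
        who_pos = who_rows.map(positive)
        ell_pos = ell_rows.map(positive)
        b = int((who_pos & ~ell_pos).sum())  # WHO positive only
        c = int((~who_pos & ell_pos).sum())  # ellipsoid positive only
        if b + c == 0:
            # fully concordant dichotomy: no discordance, no evidence
            return McNemarResult(b=0, c=0, chi2=0.0, p=1.0)
        return mcnemar(b, c)

    return RuleComparison(
        crosstab=tab,
        osteoporosis=discordant(lambda d: d == Diagnosis.OSTEOPOROSIS),
        disease=discordant(lambda d: d >= Diagnosis.OSTEOPENIA),
        who_counts=who_counts,
        ellipsoid_counts=ell_counts,
    )


def frax_group_compare(
    cohort: pd.DataFrame,
    model: CorrelationModel,
    frax_columns: tuple[str, ...] = ("frax_major", "frax_hip"),
    radii: tuple[float, float] = (1.0, 2.5),
) -> dict[str, dict[str, float]]:
    """Among WHO-osteopenic patients, compare FRAX risk between those the
    ellipsoid rule reclassifies as osteoporotic and those it does not.

    FRAX 10-year risks (percent) are consumed as input columns; they are
    never computed here.  Returns, per FRAX outcome, the two group means and
    the two-sided Welch t-test p-value.
    """
    missing = [c for c in frax_columns if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort missing FRAX column(s) {missing}")
    who_rows, _ = classify_cohort(cohort, "who")
    ell_rows, _ = classify_cohort(cohort, "ellipsoid", model=model, radii=radii)
    pen = who_rows == Diagnosis.OSTEOPENIA
    reclassified = pen & (ell_rows == Diagnosis.OSTEOPOROSIS)
    not_reclassified = pen & (ell_rows != Diagnosis.OSTEOPOROSIS)
    if not reclassified.any():
        raise ValueError("empty group: no WHO-osteopenic patient is ellipsoid-osteoporotic")
    if not not_reclassified.any():
        raise ValueError("empty group: every WHO-osteopenic patient is ellipsoid-osteoporotic")

    results: dict[str, dict[str, float]] = {}
    for col in frax_columns:
        a = cohort.loc[reclassified, col].astype(float)
        b = cohort.loc[not_reclassified, col].astype(float)
        if np.allclose(a.var(ddof=1) if len(a) > 1 else 0.0, 0.0) and np.allclose(
            b.var(ddof=1) if len(b) > 1 else 0.0, 0.0
        ) and math.isclose(a.mean(), b.mean()):
            p = 1.0  # identical degenerate groups: no evidence of difference
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        results[col] = {
            "mean_reclassified": float(a.mean()),
            "mean_not_reclassified": float(b.mean()),
            "n_reclassified": int(len(a)),
            "n_not_reclassified": int(len(b)),
            "p": p,
        }
    return results
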