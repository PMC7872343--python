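"""Young-adult reference model and BMD <-> T-score conversion.

A DXA T-score expresses a patient's areal bone mineral density (BMD, g/cm^2)
at one skeletal site as a number of young-adult standard deviations below or
above the young-adult mean at that site:

    T = (BMD - mean_young) / sd_young

The three sites used clinically are the L1-L4 lumbar spine, the femoral neck
and the total hip.  Reference means and SDs differ by site, sex and DXA
manufacturer, so they are always supplied by the user (e.g. from a NHANES III
derived panel shipped with the densitometer); this package hard-codes none.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "SITES",
    "InvalidReferenceError",
    "SiteReference",
    "ReferencePanel",
    "TScoreVector",
    "compute_tscore",
    "tscore_to_bmd",
]

#: Canonical site order used throughout the package: index 0 is the L1-L4
#: lumbar spine, 1 the femoral neck, 2 the total hip.
SITES = ("L1L4", "femoral_neck", "total_hip")


class InvalidReferenceError(ValueError):
    """Raised when a young-adult reference is unusable (e.g. sd <= 0)."""


@dataclass(frozen=True)
class SiteReference:
    """Young-adult reference distribution for one skeletal site.

    Parameters
    ----------
    site_label
        One of ``"L1L4"``, ``"femoral_neck"``, ``"total_hip"``.
    mean_bmd, sd_bmd
        Young-adult mean and standard deviation of areal BMD in g/cm^2.
    sample_size
        Number of young adults behind the estimates.  ``math.inf`` (the
        default) means the reference is treated as exactly known, which
        yields the normal-theory limit downstream.
    """

    site_label: str
    mean_bmd: float
    sd_bmd: float
    sample_size: float = math.inf

    def __post_init__(self) -> None:
        if self.site_label not in SITES:
            raise InvalidReferenceError(
                f"unknown site label {self.site_label!r}; expected one of {SITES}"
            )
        if not (self.mean_bmd > 0 and math.isfinite(self.mean_bmd)):
            raise InvalidReferenceError("reference mean BMD must be finite and > 0")
        if not (self.sd_bmd > 0 and math.isfinite(self.sd_bmd)):
            raise InvalidReferenceError("reference SD of BMD must be finite and > 0")
        m = self.sample_size
        if math.isfinite(m):
            if m != int(m) or m < 2:
                raise InvalidReferenceError(
                    "finite reference sample size must be an integer >= 2"
                )


def compute_tscore(bmd: float, ref: SiteReference) -> float:
    """T-score of a BMD measurement against a young-adult reference."""
    return (bmd - ref.mean_bmd) / ref.sd_bmd


def tscore_to_bmd(t: float, ref: SiteReference) -> float:
    """Inverse of :func:`compute_tscore`: the BMD at a given T-score."""
    return ref.mean_bmd + t * ref.sd_bmd


@dataclass(frozen=True)
class TScoreVector:
    """The complete triple of T-scores (spine, femoral neck, total hip).

    All three components are required and must be finite: the multivariate
    rule has no provision for missing sites.
    """

    t_spine: float
    t_neck: float
    t_hip: float

    def __post_init__(self) -> None:
        for name in ("t_spine", "t_neck", "t_hip"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"T-score component {name} must be finite, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.t_spine, self.t_neck, self.t_hip], dtype=float)


@dataclass(frozen=True)
class ReferencePanel:
    """Three site references plus the inter-site correlation model.

    The panel is the full young-adult model: per-site means/SDs give the
    T-score transform, and the correlation model (see
    :class:`triscore.mvt.CorrelationModel`) gives the joint scale structure
    of the T-score vector.
    """

    refs: tuple[SiteReference, SiteReference, SiteReference]
    correlation: "CorrelationModel"  # noqa: F821 - imported lazily below

    def __post_init__(self) -> None:
        labels = [r.site_label for r in self.refs]
        if sorted(labels) != sorted(SITES):
            raise InvalidReferenceError(
                f"panel must contain exactly one reference per site, got {labels}"
            )
        # keep canonical site order regardless of input order
        ordered = tuple(sorted(self.refs, key=lambda r: SITES.index(r.site_label)))
        object.__setattr__(self, "refs", ordered)

    def tscores(self, bmd_spine: float, bmd_neck: float, bmd_hip: float) -> TScoreVector:
        vals = [compute_tscore(b, r) for b, r in zip((bmd_spine, bmd_neck, bmd_hip), self.refs)]
        return TScoreVector(*vals)

    @classmethod
    def from_config(cls, source: str | Path | Mapping) -> "ReferencePanel":
        """Load a panel from a JSON/YAML file or an already-parsed mapping.

        Expected layout::

            sites:
              L1L4:          {mean: 1.18, sd: 0.12, n: 1000}   # n optional
              femoral_neck:  {mean: 0.94, sd: 0.12}
              total_hip:     {mean: 0.98, sd: 0.12}
            correlation:     {rho12: 0.66, rho13: 0.61, rho23: 0.75}
        """
        from .mvt import CorrelationModel

        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
            if str(source).endswith((".yaml", ".yml")):
                import yaml

                cfg = yaml.safe_load(text)
            else:
                cfg = json.loads(text)
        else:
            cfg = dict(source)

        try:
            site_cfg = cfg["sites"]
            corr_cfg = cfg["correlation"]
        except KeyError as exc:
            raise InvalidReferenceError(f"panel config missing section {exc}") from exc

        refs = []
        for label in SITES:
            try:
                entry = site_cfg[label]
            except KeyError:
                raise InvalidReferenceError(f"panel config missing site {label!r}")
            refs.append(
                SiteReference(
                    site_label=label,
                    mean_bmd=float(entry["mean"]),
                    sd_bmd=float(entry["sd"]),
                    sample_size=float(entry.get("n", math.inf)),
                )
            )
        model = CorrelationModel(
            rho12=float(corr_cfg["rho12"]),
            rho13=float(corr_cfg["rho13"]),
            rho23=float(corr_cfg["rho23"]),
        )
        return cls(refs=tuple(refs), correlation=model)
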