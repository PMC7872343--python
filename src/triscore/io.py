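"""Cohort CSV round-trip, run configs, and ellipsoid mesh export.

Cohort CSV schema (UTF-8, period decimal separator, header required)::

    patient_id,t_l1l4,t_fneck,t_thip[,frax_major,frax_hip,diabetes,prior_fx,supplement]

Unicode minus signs (U+2212), as pasted from publications, are normalized to
ASCII on input.  Extra columns are preserved.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import T_COLUMNS
from .mvt import CorrelationModel

__all__ = [
    "SchemaError",
    "read_cohort_csv",
    "write_cohort_csv",
    "ellipsoid_mesh",
    "write_mesh_csv",
    "load_run_config",
]

REQUIRED_COLUMNS = ("patient_id",) + T_COLUMNS


class SchemaError(ValueError):
    """Raised when a cohort file does not match the documented schema."""


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table, validating the schema.

    Raises :class:`SchemaError` naming any missing required column, or a
    row-level error with the 1-based file line number for a non-numeric
    T-score.
    """
    table = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort file {path} missing required column(s): {missing}")
    for col in T_COLUMNS:
        raw = table[col].str.replace("−", "-", regex=False)
        values = pd.to_numeric(raw, errors="coerce")
        bad = values.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"non-numeric T-score {table.loc[row, col]!r} in column {col!r} "
                f"at line {row + 2} of {path}"
            )
        table[col] = values.astype(float)
    # best-effort numeric conversion of optional columns
    for col in table.columns:
        if col not in T_COLUMNS:
            converted = pd.to_numeric(table[col], errors="coerce")
            if not converted.isna().any():
                table[col] = converted
    return table


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write a cohort table; floats at 12 significant digits (lossless
    round-trip of T-scores through :func:`read_cohort_csv`)."""
    table.to_csv(path, index=False, float_format="%.12g")


def ellipsoid_mesh(model: CorrelationModel, radius: float, resolution: int = 40) -> np.ndarray:
    """Points on the Mahalanobis sphere d(x) = radius, as an (resolution^2, 3)
    array.

    A latitude/longitude grid of unit vectors u is mapped through
    x = radius * R^{1/2} u, so every point satisfies x^T R^{-1} x = radius^2
    exactly.  Suitable for plotting the diagnostic ellipsoid boundary in
    external tools.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if resolution < 8:
        raise ValueError("resolution must be >= 8")
    theta = np.linspace(0.0, np.pi, resolution)  # polar
    phi = np.linspace(0.0, 2.0 * np.pi, resolution, endpoint=False)
    th, ph = np.meshgrid(theta, phi, indexing="ij")
    u = np.stack(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)], axis=-1
    ).reshape(-1, 3)
    S = model.sqrt("symmetric_sqrt")
    return radius * (u @ S.T)


def write_mesh_csv(points: np.ndarray, path) -> None:
    frame = pd.DataFrame(np.asarray(points, dtype=float), columns=["x", "y", "z"])
    frame.to_csv(path, index=False, float_format="%.12g")


def load_run_config(path) -> dict:
    """Load a JSON or YAML run-config mapping."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, Mapping):
        raise SchemaError(f"run config {path} must be a mapping")
    return dict(cfg)
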