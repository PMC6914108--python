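"""Cohort schema: the tabular contract every pipeline stage shares.

A cohort is a :class:`pandas.DataFrame` with one row per patient carrying a
binary treatment indicator (patient-portal registration), patient- and
provider-level covariates, four binary preventive-behavior outcomes, and
four chronic-health outcomes (two continuous, possibly missing; two binary).
The composite prevention score is the row sum of the four behavior
indicators and is derived, never stored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ID_COL = "id"
TREAT_COL = "treated"

CONTINUOUS_COVARIATES = ["age", "income"]

#: nominal covariate -> allowed levels, first level = reference for coding
NOMINAL_LEVELS: dict[str, list[str]] = {
    "sex": ["female", "male"],
    "race": ["white", "black", "hispanic", "other"],
    "insurance": ["commercial", "medicaid", "medicare", "none"],
}

#: provider indicators are stored 0/1 and treated as two-level nominals
BINARY_COVARIATES = ["prov_faculty", "prov_physician", "prov_male"]

COVARIATES = CONTINUOUS_COVARIATES + list(NOMINAL_LEVELS) + BINARY_COVARIATES

BEHAVIOR_OUTCOMES = ["flu", "bp_test", "ldl_test", "crc_test"]
CONTINUOUS_OUTCOMES = ["sbp", "ldl"]  # may be missing (NaN / empty string)
BINARY_CHRONIC_OUTCOMES = ["diabetes", "hypertension"]
COMPOSITE = "composite"

#: outcomes analysed by default, in report order
DEFAULT_OUTCOMES = (
    BEHAVIOR_OUTCOMES + [COMPOSITE] + CONTINUOUS_OUTCOMES + BINARY_CHRONIC_OUTCOMES
)

REQUIRED_COLUMNS = (
    [ID_COL, TREAT_COL]
    + COVARIATES
    + BEHAVIOR_OUTCOMES
    + CONTINUOUS_OUTCOMES
    + BINARY_CHRONIC_OUTCOMES
)

_BINARY_01 = [TREAT_COL] + BINARY_COVARIATES + BEHAVIOR_OUTCOMES + BINARY_CHRONIC_OUTCOMES


class SchemaError(ValueError):
    """A cohort table violates the declared schema."""


def composite_score(cohort: pd.DataFrame) -> pd.Series:
    """Composite prevention score: sum of the four behavior indicators (0-4)."""
    return cohort[BEHAVIOR_OUTCOMES].sum(axis=1)


def is_binary_outcome(name: str) -> bool:
    return name in BEHAVIOR_OUTCOMES or name in BINARY_CHRONIC_OUTCOMES


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check column presence, level membership and 0/1 coding.

    Returns the (unmodified) frame so calls can be chained; raises
    :class:`SchemaError` naming the offending column otherwise.
    """
    for col in REQUIRED_COLUMNS:
        if col not in cohort.columns:
            raise SchemaError(f"missing required column: {col!r}")
    for col, levels in NOMINAL_LEVELS.items():
        bad = set(cohort[col].dropna().unique()) - set(levels)
        if bad:
            raise SchemaError(f"unknown level(s) {sorted(bad)!r} in column {col!r}")
    for col in _BINARY_01:
        vals = pd.unique(cohort[col].dropna())
        if not np.isin(vals, [0, 1]).all():
            raise SchemaError(f"column {col!r} must be coded 0/1")
    return cohort


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV; missing continuous outcomes become empty cells."""
    validate_cohort(cohort)
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(
        path,
        dtype={col: "int64" for col in _BINARY_01 + [ID_COL]},
        keep_default_na=False,
        na_values=[""],
    )
    return validate_cohort(df)


def arm_indices(cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Positional indices of the treated and control rows."""
    t = np.flatnonzero(cohort[TREAT_COL].to_numpy() == 1)
    c = np.flatnonzero(cohort[TREAT_COL].to_numpy() == 0)
    return t, c
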