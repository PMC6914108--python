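"""Covariate-balance diagnostics: study-table summaries before/after matching.

Continuous covariates are summarized as mean (SD) and compared by Welch's
two-sample t test; each level of a nominal covariate is summarized as
count (percent) and compared by a chi-square test of the level-vs-rest
2x2 table (no continuity correction; Fisher's exact test when an expected
count drops below 5). P values are Bonferroni-adjusted over all rows of
the table. The standardized difference uses the matching-literature pooled
SD, sqrt((var_t + var_c)/2), the same convention the cardinality-matching
integer program enforces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    BINARY_COVARIATES,
    CONTINUOUS_COVARIATES,
    COVARIATES,
    NOMINAL_LEVELS,
    arm_indices,
)

#: sentinel for a mean difference over a zero pooled SD
INFINITE_IMBALANCE = np.inf


@dataclass(frozen=True)
class BalanceRow:
    """One table row: a continuous covariate or one nominal level.

    For ``kind == "continuous"`` the stats are (mean, sd); for
    ``kind == "level"`` they are (count, percent). ``mean_diff`` keeps the
    raw between-arm mean/proportion difference so balance assertions can be
    evaluated against an external reference SD.
    """

    variable: str
    level: str | None
    kind: str  # "continuous" | "level"
    treated_stat1: float
    treated_stat2: float
    control_stat1: float
    control_stat2: float
    smd: float
    mean_diff: float
    p_value: float
    p_adjusted: float = np.nan

    @property
    def label(self) -> str:
        return self.variable if self.level is None else f"{self.variable}={self.level}"


def standardized_difference(x_treated, x_control) -> float:
    """(mean_t - mean_c) / sqrt((var_t + var_c)/2), sample (ddof=1) variances."""
    x_t = np.asarray(x_treated, dtype=float)
    x_c = np.asarray(x_control, dtype=float)
    if x_t.size == 0 or x_c.size == 0:
        raise ValueError("both arms must be non-empty")
    diff = x_t.mean() - x_c.mean()
    var_t = x_t.var(ddof=1) if x_t.size > 1 else 0.0
    var_c = x_c.var(ddof=1) if x_c.size > 1 else 0.0
    pooled = np.sqrt((var_t + var_c) / 2.0)
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        warnings.warn("zero pooled SD with unequal means: infinite imbalance")
        return np.sign(diff) * INFINITE_IMBALANCE
    return float(diff / pooled)


def _level_test(a: int, n_t: int, b: int, n_c: int) -> float:
    """P value for one nominal level: level-vs-rest 2x2 comparison."""
    if a == 0 and b == 0:
        return 1.0
    table = np.array([[a, n_t - a], [b, n_c - b]], dtype=float)
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        return float(stats.fisher_exact(table.astype(int))[1])
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def _continuous_row(name: str, x_t: np.ndarray, x_c: np.ndarray) -> BalanceRow:
    smd = standardized_difference(x_t, x_c)
    if smd == 0.0 and x_t.std() == 0.0 and x_c.std() == 0.0:
        p = 1.0
    else:
        p = float(stats.ttest_ind(x_t, x_c, equal_var=False).pvalue)
        if np.isnan(p):
            p = 1.0
    return BalanceRow(
        variable=name,
        level=None,
        kind="continuous",
        treated_stat1=float(x_t.mean()),
        treated_stat2=float(x_t.std(ddof=1)) if x_t.size > 1 else 0.0,
        control_stat1=float(x_c.mean()),
        control_stat2=float(x_c.std(ddof=1)) if x_c.size > 1 else 0.0,
        smd=smd,
        mean_diff=float(x_t.mean() - x_c.mean()),
        p_value=p,
    )


def _level_row(
    variable: str, level: str, ind_t: np.ndarray, ind_c: np.ndarray
) -> BalanceRow:
    a, b = int(ind_t.sum()), int(ind_c.sum())
    n_t, n_c = ind_t.size, ind_c.size
    return BalanceRow(
        variable=variable,
        level=level,
        kind="level",
        treated_stat1=a,
        treated_stat2=100.0 * a / n_t,
        control_stat1=b,
        control_stat2=100.0 * b / n_c,
        smd=standardized_difference(ind_t, ind_c),
        mean_diff=a / n_t - b / n_c,
        p_value=_level_test(a, n_t, b, n_c),
    )


def balance_table(
    cohort: pd.DataFrame,
    selection: str | tuple = "all",
    variables: list[str] | None = None,
) -> list[BalanceRow]:
    """Balance rows for the given covariates on the full cohort or a selection.

    ``selection`` is ``"all"`` or a ``(treated_positions, control_positions)``
    pair of positional index arrays (disjoint, each within its arm).
    """
    variables = list(COVARIATES) if variables is None else list(variables)
    if selection == "all":
        t_idx, c_idx = arm_indices(cohort)
    else:
        t_idx = np.asarray(selection[0], dtype=int)
        c_idx = np.asarray(selection[1], dtype=int)
        if np.intersect1d(t_idx, c_idx).size:
            raise ValueError("treated and control selections overlap")
    if t_idx.size == 0 or c_idx.size == 0:
        raise ValueError("both arms must be non-empty")

    rows: list[BalanceRow] = []
    for var in variables:
        if var in CONTINUOUS_COVARIATES:
            x = cohort[var].to_numpy(dtype=float)
            rows.append(_continuous_row(var, x[t_idx], x[c_idx]))
        elif var in NOMINAL_LEVELS:
            vals = cohort[var].to_numpy()
            for lev in NOMINAL_LEVELS[var]:
                rows.append(
                    _level_row(var, lev, (vals[t_idx] == lev).astype(float),
                               (vals[c_idx] == lev).astype(float))
                )
        elif var in BINARY_COVARIATES:
            x = cohort[var].to_numpy(dtype=float)
            rows.append(_level_row(var, "1", x[t_idx], x[c_idx]))
        else:
            raise KeyError(f"unknown covariate {var!r}")

    k = len(rows)
    return [
        BalanceRow(**{**row.__dict__, "p_adjusted": min(1.0, row.p_value * k)})
        for row in rows
    ]


@dataclass(frozen=True)
class BalanceReport:
    """Pass/fail verdict of a balance assertion, with per-failure messages."""

    passed: bool
    failures: list[str] = field(default_factory=list)


def assert_balance(
    table: list[BalanceRow],
    spec,
    reference_sd: dict[str, float] | None = None,
) -> BalanceReport:
    """Check a (post-match) balance table against a :class:`BalanceSpec`.

    Moment covariates must have |mean difference| <= tolerance x reference
    SD (the table's own pooled SD when no reference is given); fine-balance
    covariates must have exactly equal level counts between arms. A small
    slack absorbs solver integrality tolerance.
    """
    failures: list[str] = []
    by_label = {row.label: row for row in table}
    for cov in spec.moment_covariates:
        row = by_label.get(cov)
        if row is None:
            failures.append(f"moment covariate {cov!r} missing from table")
            continue
        if reference_sd and cov in reference_sd:
            sd = reference_sd[cov]
            gap = abs(row.mean_diff) - spec.moment_tolerance * sd
            # slack: solver integrality tolerance propagated through the mean
            if gap > 1e-6 * max(sd, 1.0):
                failures.append(
                    f"{cov}: |mean diff| {abs(row.mean_diff):.6g} exceeds "
                    f"{spec.moment_tolerance} x SD {sd:.6g}"
                )
        elif abs(row.smd) > spec.moment_tolerance + 1e-6:
            failures.append(f"{cov}: |SMD| {abs(row.smd):.4f} > {spec.moment_tolerance}")
    for cov in spec.fine_covariates:
        for row in table:
            if row.variable == cov and row.kind == "level":
                if int(round(row.treated_stat1)) != int(round(row.control_stat1)):
                    failures.append(
                        f"{cov}={row.level}: counts {int(row.treated_stat1)} vs "
                        f"{int(row.control_stat1)} not fine-balanced"
                    )
    return BalanceReport(passed=not failures, failures=failures)


def balance_frame(table: list[BalanceRow]) -> pd.DataFrame:
    """Balance table as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "variable": [r.variable for r in table],
            "level": [r.level if r.level is not None else "" for r in table],
            "kind": [r.kind for r in table],
            "treated_mean_or_count": [r.treated_stat1 for r in table],
            "treated_sd_or_pct": [r.treated_stat2 for r in table],
            "control_mean_or_count": [r.control_stat1 for r in table],
            "control_sd_or_pct": [r.control_stat2 for r in table],
            "smd": [r.smd for r in table],
            "p_value": [r.p_value for r in table],
            "p_adjusted": [r.p_adjusted for r in table],
        }
    )


def format_table(table: list[BalanceRow], title: str = "") -> str:
    """Aligned-text rendering in the familiar study-table layout."""
    lines = []
    if title:
        lines.append(title)
    header = f"{'Variable':<26}{'Treated':>22}{'Control':>22}{'SMD':>9}{'P adj':>9}"
    lines.append(header)
    lines.append("-" * len(header))
    for r in table:
        if r.kind == "continuous":
            t = f"{r.treated_stat1:,.2f} ({r.treated_stat2:,.2f})"
            c = f"{r.control_stat1:,.2f} ({r.control_stat2:,.2f})"
        else:
            t = f"{int(r.treated_stat1)} ({r.treated_stat2:.2f})"
            c = f"{int(r.control_stat1)} ({r.control_stat2:.2f})"
        p = ">.99" if r.p_adjusted > 0.99 else f"{r.p_adjusted:.3f}"
        lines.append(f"{r.label:<26}{t:>22}{c:>22}{r.smd:>9.3f}{p:>9}")
    return "\n".join(lines) + "\n"
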