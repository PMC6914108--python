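"""Cardinality matching: maximum-size balanced subsets via integer programming.

Step 1 of the two-step matched design. One binary decision variable per
patient selects them into the match. The objective maximizes the number of
selected treated patients subject to

* equal group sizes,
* moment balance — for each continuous covariate, selected-group means at
  most ``moment_tolerance`` reference SDs apart, linearized as
  ``|sum_t x a - sum_c x a| <= tol * sigma * m`` with ``m`` the (variable)
  match size,
* fine balance — identical marginal level counts of each nominal covariate
  between groups, without pairing within levels.

The program is solved with HiGHS through :func:`scipy.optimize.milp`.
The empty selection is always feasible, so a solve can return cardinality
zero but never infeasibility for a positive tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, milp

from .balance import BalanceRow, balance_table
from .cohort import (
    BINARY_COVARIATES,
    CONTINUOUS_COVARIATES,
    NOMINAL_LEVELS,
    arm_indices,
)

logger = logging.getLogger(__name__)

DEFAULT_MOMENT_COVARIATES = ["age", "income"]
DEFAULT_FINE_COVARIATES = ["sex", "race", "insurance",
                           "prov_faculty", "prov_physician", "prov_male"]

INTEGRALITY_TOL = 1e-6


@dataclass(frozen=True)
class BalanceSpec:
    """Balance requirements the integer program enforces."""

    moment_covariates: list[str] = field(
        default_factory=lambda: list(DEFAULT_MOMENT_COVARIATES))
    moment_tolerance: float = 0.05
    fine_covariates: list[str] = field(
        default_factory=lambda: list(DEFAULT_FINE_COVARIATES))
    sd_reference: str = "full-sample"  # or "treated-sample"

    def __post_init__(self):
        if self.moment_tolerance < 0:
            raise ValueError("moment_tolerance must be >= 0")
        overlap = set(self.moment_covariates) & set(self.fine_covariates)
        if overlap:
            raise ValueError(f"covariates in both moment and fine lists: {sorted(overlap)}")
        if self.sd_reference not in ("full-sample", "treated-sample"):
            raise ValueError(f"unknown sd_reference {self.sd_reference!r}")


@dataclass(frozen=True)
class BalanceProgram:
    """The built integer program, solver-agnostic."""

    objective: np.ndarray          # maximize objective @ a
    constraints: list[LinearConstraint]
    row_labels: list[str]
    treated_mask: np.ndarray
    reference_sd: dict[str, float]

    @property
    def n_constraint_rows(self) -> int:
        return sum(np.atleast_2d(c.A).shape[0] for c in self.constraints)


@dataclass(frozen=True)
class MatchResult:
    """Selected index sets plus solver diagnostics."""

    selected_treated: np.ndarray   # positional indices into the cohort
    selected_control: np.ndarray
    cardinality: int
    solver_status: str             # optimal | feasible-time-limit | infeasible
    objective_bound: int
    achieved_balance: list[BalanceRow]
    reference_sd: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "selected_treated": self.selected_treated.tolist(),
            "selected_control": self.selected_control.tolist(),
            "cardinality": self.cardinality,
            "solver_status": self.solver_status,
            "objective_bound": self.objective_bound,
        }


def _level_values(cohort: pd.DataFrame, cov: str) -> list[tuple[str, np.ndarray]]:
    if cov in NOMINAL_LEVELS:
        vals = cohort[cov].to_numpy()
        return [(lev, (vals == lev).astype(float)) for lev in NOMINAL_LEVELS[cov]]
    if cov in BINARY_COVARIATES:
        x = cohort[cov].to_numpy(dtype=float)
        return [("0", 1.0 - x), ("1", x)]
    raise KeyError(f"{cov!r} is not a nominal covariate")


def reference_sds(cohort: pd.DataFrame, spec: BalanceSpec) -> dict[str, float]:
    """The SD anchoring each moment-balance tolerance."""
    if spec.sd_reference == "treated-sample":
        base = cohort.loc[cohort["treated"] == 1]
    else:
        base = cohort
    return {cov: float(base[cov].std(ddof=1)) for cov in spec.moment_covariates}


def build_balance_program(cohort: pd.DataFrame, spec: BalanceSpec) -> BalanceProgram:
    """Assemble objective and constraint rows; no solver involved."""
    t_idx, c_idx = arm_indices(cohort)
    if t_idx.size == 0 or c_idx.size == 0:
        raise ValueError("both arms must be non-empty")
    n = len(cohort)
    treated = np.zeros(n)
    treated[t_idx] = 1.0
    control = 1.0 - treated

    sds = reference_sds(cohort, spec)
    constraints: list[LinearConstraint] = []
    labels: list[str] = []

    # equal selected group sizes
    constraints.append(LinearConstraint(treated - control, 0.0, 0.0))
    labels.append("equal-size")

    for cov in spec.moment_covariates:
        if cov not in cohort.columns:
            raise KeyError(f"moment covariate {cov!r} not in cohort")
        x = cohort[cov].to_numpy(dtype=float)
        sigma = sds[cov]
        if sigma == 0.0:
            logger.warning("covariate %r has zero SD; moment constraint "
                           "degenerates to exact mean equality", cov)
        tol = spec.moment_tolerance * sigma
        signed = x * treated - x * control
        # sum_t x a - sum_c x a - tol * m <= 0  and the mirrored row
        constraints.append(LinearConstraint(signed - tol * treated, -np.inf, 0.0))
        constraints.append(LinearConstraint(-signed - tol * treated, -np.inf, 0.0))
        labels += [f"moment+:{cov}", f"moment-:{cov}"]

    for cov in spec.fine_covariates:
        if cov not in cohort.columns:
            raise KeyError(f"fine covariate {cov!r} not in cohort")
        for lev, ind in _level_values(cohort, cov):
            constraints.append(LinearConstraint(ind * treated - ind * control, 0.0, 0.0))
            labels.append(f"fine:{cov}={lev}")

    return BalanceProgram(
        objective=treated,
        constraints=constraints,
        row_labels=labels,
        treated_mask=treated.astype(bool),
        reference_sd=sds,
    )


def solve_cardinality(
    cohort: pd.DataFrame,
    spec: BalanceSpec | None = None,
    time_limit_s: float | None = None,
    seed: int = 0,
) -> MatchResult:
    """Solve the balance program for the maximum-cardinality selection.

    ``seed`` is accepted for interface stability; the HiGHS solve is
    deterministic for a fixed program and time limit.
    """
    spec = BalanceSpec() if spec is None else spec
    program = build_balance_program(cohort, spec)
    n = len(cohort)
    # root-LP presolve costs far more than it saves on these wide, shallow
    # programs (a handful of rows, thousands of binaries)
    options = {"presolve": False}
    if time_limit_s is not None:
        options["time_limit"] = float(time_limit_s)
    res = milp(
        c=-program.objective,
        constraints=program.constraints,
        integrality=np.ones(n),
        bounds=Bounds(0.0, 1.0),
        options=options,
    )

    if res.x is None:
        # no incumbent: report the (always feasible) empty match
        logger.warning("solver returned no incumbent (status %s); empty match", res.status)
        status = "infeasible" if res.status == 2 else "feasible-time-limit"
        empty = np.array([], dtype=int)
        return MatchResult(empty, empty, 0, status, n, [], program.reference_sd)

    a = res.x > 0.5
    sel_t = np.flatnonzero(a & program.treated_mask)
    sel_c = np.flatnonzero(a & ~program.treated_mask)
    cardinality = sel_t.size
    status = "optimal" if res.status == 0 else "feasible-time-limit"
    bound = int(np.floor(-res.mip_dual_bound + INTEGRALITY_TOL)) if res.status != 0 else cardinality
    if cardinality == 0:
        logger.warning("cardinality-zero match: balance constraints admit no pairs")
        achieved: list[BalanceRow] = []
    else:
        achieved = balance_table(
            cohort, (sel_t, sel_c), spec.moment_covariates + spec.fine_covariates
        )
    return MatchResult(
        selected_treated=sel_t,
        selected_control=sel_c,
        cardinality=int(cardinality),
        solver_status=status,
        objective_bound=bound,
        achieved_balance=achieved,
        reference_sd=program.reference_sd,
    )


def greedy_caliper_baseline(
    cohort: pd.DataFrame, logit_scores: np.ndarray, caliper_width: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy 1:1 nearest-neighbor matching on the logit propensity score.

    The conventional baseline design: treated patients in descending score
    order each take the closest unused control within ``caliper_width`` SDs
    of the logit score, or go unmatched. Returns the matched treated and
    control positional indices.
    """
    t_idx, c_idx = arm_indices(cohort)
    cal = caliper_width * np.std(logit_scores, ddof=1)
    order = t_idx[np.argsort(-logit_scores[t_idx], kind="stable")]
    controls = c_idx[np.argsort(logit_scores[c_idx], kind="stable")]
    available = np.ones(controls.size, dtype=bool)
    c_scores = logit_scores[controls]
    matched_t, matched_c = [], []
    for ti in order:
        gaps = np.abs(c_scores - logit_scores[ti])
        gaps[~available] = np.inf
        j = int(np.argmin(gaps))
        if gaps[j] <= cal:
            available[j] = False
            matched_t.append(ti)
            matched_c.append(controls[j])
    return np.asarray(matched_t, dtype=int), np.asarray(matched_c, dtype=int)
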