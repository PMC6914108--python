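"""Optimal 1:1 pairing within fixed matched groups.

Step 2 of the matched design: with the treated and control groups fixed by
cardinality matching, form disjoint pairs minimizing the total rank-based
robust Mahalanobis distance, with an additive penalty for pairs whose
logit propensity scores differ by more than a caliper. Covariates enter as
midranks over the pooled selected units, which bounds the influence of
outliers and makes the distance invariant to monotone transforms. The
pairing itself is a linear assignment problem solved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .cohort import BINARY_COVARIATES, CONTINUOUS_COVARIATES, NOMINAL_LEVELS
from .propensity import PropensityFit

logger = logging.getLogger(__name__)

RIDGE = 1e-8  # diagonal regularization, times trace(S)/p

DEFAULT_DISTANCE_COVARIATES = ["age", "income", "sex", "race", "insurance",
                               "prov_faculty", "prov_physician", "prov_male"]


@dataclass(frozen=True)
class PairingConfig:
    """Distance and caliper settings for the pairing step."""

    caliper_width: float = 0.2        # in SDs of the logit propensity score
    penalty_scale: float | None = None  # default: 1000 x mean unpenalized distance
    distance_on: str = "covariates"   # or "propensity"
    distance_covariates: list[str] = field(
        default_factory=lambda: list(DEFAULT_DISTANCE_COVARIATES))


@dataclass(frozen=True)
class DistanceMatrix:
    """Treated x control distances over a matched selection."""

    matrix: np.ndarray
    treated_index: np.ndarray   # cohort positions, row order
    control_index: np.ndarray   # cohort positions, column order
    caliper_width: float | None = None
    penalty_scale: float | None = None


@dataclass(frozen=True)
class PairSet:
    """Disjoint treated-control pairs and their total distance."""

    pairs: list[tuple[int, int]]  # (treated cohort position, control cohort position)
    total_distance: float

    @property
    def treated_index(self) -> np.ndarray:
        return np.asarray([t for t, _ in self.pairs], dtype=int)

    @property
    def control_index(self) -> np.ndarray:
        return np.asarray([c for _, c in self.pairs], dtype=int)

    def to_frame(self, fit: PropensityFit | None = None,
                 distances: DistanceMatrix | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.pairs, columns=["treated_id", "control_id"])
        if distances is not None:
            row = {int(t): i for i, t in enumerate(distances.treated_index)}
            col = {int(c): j for j, c in enumerate(distances.control_index)}
            df["distance"] = [
                distances.matrix[row[t], col[c]] for t, c in self.pairs
            ]
        if fit is not None:
            df["ps_gap"] = [
                abs(fit.scores[t] - fit.scores[c]) for t, c in self.pairs
            ]
        return df


def rank_transform(columns: np.ndarray) -> np.ndarray:
    """Column-wise midranks (ties get the average rank) over the pooled rows."""
    X = np.atleast_2d(np.asarray(columns, dtype=float))
    return rankdata(X, axis=0, method="average")


def robust_mahalanobis(
    ranks: np.ndarray, treated_index: np.ndarray, control_index: np.ndarray
) -> DistanceMatrix:
    """Unpenalized Mahalanobis distances on the rank scale.

    ``ranks`` holds the pooled selected units (rows); the covariance of
    those rows defines the metric, lightly ridge-regularized. All-constant
    columns carry no information and are dropped with a warning.
    """
    R = np.asarray(ranks, dtype=float)
    keep = R.std(axis=0) > 0
    if not keep.all():
        logger.warning("dropping %d all-constant rank column(s)", (~keep).sum())
        R = R[:, keep]
    if R.shape[1] == 0:
        t = np.asarray(treated_index, dtype=int)
        c = np.asarray(control_index, dtype=int)
        return DistanceMatrix(np.zeros((t.size, c.size)), t, c)
    p = R.shape[1]
    S = np.cov(R, rowvar=False).reshape(p, p)
    S = S + np.eye(p) * (RIDGE * np.trace(S) / p)
    L = np.linalg.cholesky(S)
    # whiten: d(i,j) = Euclidean distance between solved coordinates
    Z = np.linalg.solve(L, R.T).T
    t = np.asarray(treated_index, dtype=int)
    c = np.asarray(control_index, dtype=int)
    D = cdist(Z[t], Z[c])
    return DistanceMatrix(D, t, c)


def apply_caliper(
    D: DistanceMatrix,
    fit: PropensityFit,
    width: float = 0.2,
    penalty_scale: float | None = None,
) -> DistanceMatrix:
    """Additive penalty for logit-propensity gaps beyond ``width`` SDs.

    The caliper is soft: violating pairs stay available but pay
    ``penalty_scale`` per unit of excess gap, steering the assignment
    toward propensity-comparable pairs without ever making it infeasible.
    """
    if width <= 0:
        raise ValueError("caliper width must be > 0")
    if penalty_scale is None:
        penalty_scale = 1000.0 * float(D.matrix.mean())
    logits = fit.logit_scores
    sd = float(np.std(logits, ddof=1))
    gaps = np.abs(logits[D.treated_index][:, None] - logits[D.control_index][None, :])
    excess = np.maximum(0.0, gaps - width * sd)
    return DistanceMatrix(
        matrix=D.matrix + penalty_scale * excess,
        treated_index=D.treated_index,
        control_index=D.control_index,
        caliper_width=width,
        penalty_scale=penalty_scale,
    )


def min_cost_pairing(D: DistanceMatrix) -> PairSet:
    """Globally optimal perfect pairing (linear assignment, not greedy)."""
    M = D.matrix
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"distance matrix must be square, got {M.shape}")
    rows, cols = linear_sum_assignment(M)
    pairs = [
        (int(D.treated_index[i]), int(D.control_index[j]))
        for i, j in zip(rows, cols)
    ]
    return PairSet(pairs=pairs, total_distance=float(M[rows, cols].sum()))


def build_distance_matrix(
    cohort: pd.DataFrame,
    selected_treated: np.ndarray,
    selected_control: np.ndarray,
    fit: PropensityFit,
    config: PairingConfig | None = None,
) -> DistanceMatrix:
    """Penalized rank-Mahalanobis distances for a matched selection."""
    config = PairingConfig() if config is None else config
    sel = np.concatenate([selected_treated, selected_control])
    if config.distance_on == "propensity":
        cols = fit.logit_scores[sel][:, None]
    elif config.distance_on == "covariates":
        cols = _covariate_columns(cohort, sel, config.distance_covariates)
    else:
        raise ValueError(f"unknown distance_on {config.distance_on!r}")
    ranks = rank_transform(cols)
    t_local = np.arange(selected_treated.size)
    c_local = np.arange(selected_treated.size, sel.size)
    D = robust_mahalanobis(ranks, t_local, c_local)
    D = DistanceMatrix(D.matrix, np.asarray(selected_treated), np.asarray(selected_control))
    return apply_caliper(D, fit, config.caliper_width, config.penalty_scale)


def _covariate_columns(cohort, sel, covariates) -> np.ndarray:
    cols = []
    for cov in covariates:
        if cov in CONTINUOUS_COVARIATES or cov in BINARY_COVARIATES:
            cols.append(cohort[cov].to_numpy(dtype=float)[sel])
        elif cov in NOMINAL_LEVELS:
            vals = cohort[cov].to_numpy()[sel]
            for lev in NOMINAL_LEVELS[cov][1:]:
                cols.append((vals == lev).astype(float))
        else:
            raise KeyError(f"unknown covariate {cov!r}")
    return np.column_stack(cols)
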