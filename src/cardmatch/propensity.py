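"""Propensity-score estimation: probability of portal use given covariates.

A main-effects maximum-likelihood logistic regression of the treatment
indicator on the patient- and provider-level covariates, with nominal
covariates reference-coded (reference levels: white race, commercial
insurance, female sex). If the ML fit fails to converge (e.g. complete
separation), a weakly ridge-penalized fit takes over so every patient
still receives a score strictly inside (0, 1); ``converged`` is then False.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import (
    BINARY_COVARIATES,
    CONTINUOUS_COVARIATES,
    COVARIATES,
    NOMINAL_LEVELS,
    TREAT_COL,
)

logger = logging.getLogger(__name__)

MAX_ITER = 100
LOGLIK_TOL = 1e-8
RIDGE_FALLBACK = 1e-4  # penalty on squared coefficients (not the intercept)

# clamp scores away from 0/1 so logits stay finite under separation
_EPS = 1e-12


@dataclass(frozen=True)
class PropensityFit:
    """Fitted propensity model and per-patient scores."""

    coefficients: np.ndarray
    scores: np.ndarray
    logit_scores: np.ndarray
    converged: bool
    covariate_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table for audit export."""
        return pd.DataFrame(
            {"term": self.covariate_names, "coefficient": self.coefficients}
        )


def design_matrix(
    cohort: pd.DataFrame, covariates: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Reference-coded design matrix (with intercept) for the given covariates."""
    covariates = list(COVARIATES) if covariates is None else list(covariates)
    cols: list[np.ndarray] = [np.ones(len(cohort))]
    names = ["intercept"]
    for cov in covariates:
        if cov in NOMINAL_LEVELS:
            for lev in NOMINAL_LEVELS[cov][1:]:  # first level is the reference
                cols.append((cohort[cov].to_numpy() == lev).astype(float))
                names.append(f"{cov}={lev}")
        elif cov in CONTINUOUS_COVARIATES or cov in BINARY_COVARIATES:
            cols.append(cohort[cov].to_numpy(dtype=float))
            names.append(cov)
        else:
            raise KeyError(f"unknown covariate {cov!r}")
    return np.column_stack(cols), names


def fit_propensity(
    cohort: pd.DataFrame, covariates: list[str] | None = None
) -> PropensityFit:
    """ML logistic fit of treatment on covariates.

    Falls back to a ridge-penalized fit (strength ``RIDGE_FALLBACK``) when
    Newton iterations fail to converge within ``MAX_ITER`` steps.
    """
    y = cohort[TREAT_COL].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both treatment arms must be non-empty")
    X, names = design_matrix(cohort, covariates)
    beta, converged = _ml_fit(X, y)
    if not converged:
        logger.warning(
            "propensity ML fit did not converge; using ridge-penalized fallback"
        )
        beta = _ridge_irls(X, y, RIDGE_FALLBACK)
    eta = X @ beta
    scores = np.clip(1.0 / (1.0 + np.exp(-eta)), _EPS, 1.0 - _EPS)
    logits = np.log(scores / (1.0 - scores))
    return PropensityFit(
        coefficients=beta,
        scores=scores,
        logit_scores=logits,
        converged=converged,
        covariate_names=names,
    )


def _ml_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation / convergence warnings handled here
        try:
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=MAX_ITER, tol=LOGLIK_TOL, disp=False
            )
        except Exception:
            return np.zeros(X.shape[1]), False
    beta = np.asarray(res.params, dtype=float)
    ok = bool(res.mle_retvals.get("converged", False)) and np.isfinite(beta).all()
    # Newton can report "converged" on a separated ridge of the likelihood
    # where coefficients diverge; treat implausibly large logits as failure.
    if ok and np.abs(X @ beta).max() > 30.0:
        ok = False
    return beta, ok


def _ridge_irls(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """IRLS for logistic regression with an L2 penalty on non-intercept terms."""
    n, p = X.shape
    pen = np.full(p, alpha)
    pen[0] = 0.0
    beta = np.zeros(p)
    for _ in range(MAX_ITER):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - pen * beta
        H = (X * w[:, None]).T @ X + np.diag(pen)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    return beta
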