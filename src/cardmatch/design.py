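"""One full matched design: propensity fit -> cardinality match -> pairing."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cardinality import BalanceSpec, MatchResult, solve_cardinality
from .pairing import DistanceMatrix, PairingConfig, PairSet, build_distance_matrix, min_cost_pairing
from .propensity import PropensityFit, fit_propensity


@dataclass(frozen=True)
class DesignResult:
    """Everything one execution of the matched design produces."""

    fit: PropensityFit
    match: MatchResult
    distances: DistanceMatrix | None
    pairs: PairSet | None


def run_design(
    cohort: pd.DataFrame,
    spec: BalanceSpec | None = None,
    propensity_covariates: list[str] | None = None,
    pairing: PairingConfig | None = None,
    time_limit_s: float | None = None,
    seed: int = 0,
) -> DesignResult:
    """Execute the two-step design on a cohort.

    Returns a cardinality-zero result with no pairs when the balance
    constraints admit no matched patients.
    """
    fit = fit_propensity(cohort, propensity_covariates)
    match = solve_cardinality(cohort, spec, time_limit_s=time_limit_s, seed=seed)
    if match.cardinality == 0:
        return DesignResult(fit=fit, match=match, distances=None, pairs=None)
    D = build_distance_matrix(
        cohort, match.selected_treated, match.selected_control, fit, pairing
    )
    pairs = min_cost_pairing(D)
    return DesignResult(fit=fit, match=match, distances=D, pairs=pairs)
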