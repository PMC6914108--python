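"""Matched effect estimation with design-aware bootstrap inference.

Point estimates compare the matched groups: marginal odds ratios from
group proportions for binary outcomes, mean differences in native units
for continuous ones (including the 0-4 composite prevention score), using
every matched patient with a non-missing outcome value.

Standard errors come from a bootstrap that re-executes the entire design
per replicate — patients are resampled with replacement within each
treatment arm, then the propensity model is re-fit, the cardinality match
re-solved and the pairs re-formed before the estimates are recomputed.
Resampling fixed pairs would ignore the variability of the matching
itself (propensity estimation, selection, pairing order) and understate
the variance; re-running the design propagates it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cardinality import BalanceSpec
from .cohort import (
    COMPOSITE,
    DEFAULT_OUTCOMES,
    TREAT_COL,
    composite_score,
    is_binary_outcome,
)
from .design import run_design
from .pairing import PairingConfig, PairSet

logger = logging.getLogger(__name__)

Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class EffectEstimate:
    """Per-outcome matched estimate. ``se`` is on the log scale for ORs."""

    outcome: str
    scale: str  # "odds-ratio" | "mean-difference"
    point: float
    se: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan
    n_used: int = 0
    continuity_corrected: bool = False


@dataclass(frozen=True)
class BootstrapConfig:
    """Design-aware bootstrap settings."""

    n_replicates: int = 200
    seed: int = 0
    resampling: str = "stratified-by-arm"
    ci_method: str = "normal"  # or "percentile"

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.resampling != "stratified-by-arm":
            raise ValueError(f"unknown resampling {self.resampling!r}")
        if self.ci_method not in ("normal", "percentile"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")


def _outcome_values(cohort: pd.DataFrame, outcome: str) -> pd.Series:
    return composite_score(cohort) if outcome == COMPOSITE else cohort[outcome]


def _binary_or(y_t: np.ndarray, y_c: np.ndarray) -> tuple[float, bool]:
    """Marginal odds ratio from matched-group 2x2 counts.

    A zero cell triggers the 0.5 continuity correction on all four cells.
    """
    a, b = float(y_t.sum()), float((1 - y_t).sum())
    c, d = float(y_c.sum()), float((1 - y_c).sum())
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c), corrected


def point_estimates(
    cohort: pd.DataFrame,
    pairs: PairSet,
    outcomes: list[str] | None = None,
) -> list[EffectEstimate]:
    """Matched-group point estimates (no inference yet)."""
    outcomes = list(DEFAULT_OUTCOMES) if outcomes is None else list(outcomes)
    t_idx, c_idx = pairs.treated_index, pairs.control_index
    estimates = []
    for outcome in outcomes:
        vals = _outcome_values(cohort, outcome).to_numpy(dtype=float)
        y_t, y_c = vals[t_idx], vals[c_idx]
        if is_binary_outcome(outcome):
            point, corrected = _binary_or(y_t, y_c)
            estimates.append(EffectEstimate(
                outcome=outcome, scale="odds-ratio", point=point,
                n_used=y_t.size + y_c.size, continuity_corrected=corrected,
            ))
        else:
            y_t, y_c = y_t[~np.isnan(y_t)], y_c[~np.isnan(y_c)]
            estimates.append(EffectEstimate(
                outcome=outcome, scale="mean-difference",
                point=float(y_t.mean() - y_c.mean()),
                n_used=y_t.size + y_c.size,
            ))
    return estimates


def _resample_within_arms(cohort: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    parts = []
    for arm in (1, 0):
        block = cohort.loc[cohort[TREAT_COL] == arm]
        take = rng.integers(0, len(block), size=len(block))
        parts.append(block.iloc[take])
    return pd.concat(parts, ignore_index=True)


def pipeline_bootstrap(
    cohort: pd.DataFrame,
    spec: BalanceSpec | None = None,
    propensity_covariates: list[str] | None = None,
    pairing: PairingConfig | None = None,
    boot: BootstrapConfig | None = None,
    outcomes: list[str] | None = None,
) -> list[EffectEstimate]:
    """Full matched analysis with bootstrap SEs, CIs and p-values.

    Each replicate resamples patients with replacement within arms
    (original arm sizes preserved) and re-runs propensity fit, cardinality
    match and pairing from scratch. Replicate seeds are spawned from the
    master seed, so results do not depend on execution order. Replicates
    whose match is empty are dropped; more than 10% dropped is an error.
    """
    boot = BootstrapConfig() if boot is None else boot
    outcomes = list(DEFAULT_OUTCOMES) if outcomes is None else list(outcomes)
    design = run_design(cohort, spec, propensity_covariates, pairing)
    if design.pairs is None:
        raise RuntimeError("cardinality match of the original cohort is empty")
    points = point_estimates(cohort, design.pairs, outcomes)

    children = np.random.SeedSequence(boot.seed).spawn(boot.n_replicates)
    replicate_rows: list[np.ndarray] = []
    dropped = 0
    for child in children:
        rng = np.random.default_rng(child)
        boot_cohort = _resample_within_arms(cohort, rng)
        rep = run_design(boot_cohort, spec, propensity_covariates, pairing)
        if rep.pairs is None:
            dropped += 1
            continue
        rep_points = point_estimates(boot_cohort, rep.pairs, outcomes)
        replicate_rows.append(np.array([
            np.log(e.point) if e.scale == "odds-ratio" else e.point
            for e in rep_points
        ]))
    if dropped > 0.10 * boot.n_replicates:
        raise RuntimeError(
            f"{dropped}/{boot.n_replicates} bootstrap replicates had empty matches"
        )
    if dropped:
        logger.warning("dropped %d empty-match bootstrap replicate(s)", dropped)

    reps = np.vstack(replicate_rows)  # (B_kept, n_outcomes) on estimation scale
    out = []
    for k, est in enumerate(points):
        on_log = est.scale == "odds-ratio"
        theta = np.log(est.point) if on_log else est.point
        se = float(reps[:, k].std(ddof=1))
        if boot.ci_method == "percentile":
            lo, hi = np.percentile(reps[:, k], [2.5, 97.5])
        else:
            lo, hi = theta - Z975 * se, theta + Z975 * se
        if se == 0.0:
            lo = hi = theta
            p = 1.0 if theta == 0.0 else 0.0
        else:
            p = float(2.0 * stats.norm.sf(abs(theta) / se))
        if on_log:
            lo, hi = float(np.exp(lo)), float(np.exp(hi))
        out.append(EffectEstimate(
            outcome=est.outcome, scale=est.scale, point=est.point, se=se,
            ci_low=float(lo), ci_high=float(hi), p_value=p,
            n_used=est.n_used, continuity_corrected=est.continuity_corrected,
        ))
    return out


def effects_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    """Effects table as a DataFrame (CSV-ready)."""
    return pd.DataFrame({
        "outcome": [e.outcome for e in estimates],
        "scale": [e.scale for e in estimates],
        "n": [e.n_used for e in estimates],
        "estimate": [e.point for e in estimates],
        "se": [e.se for e in estimates],
        "ci_low": [e.ci_low for e in estimates],
        "ci_high": [e.ci_high for e in estimates],
        "p_value": [e.p_value for e in estimates],
    })


def format_effects(estimates: list[EffectEstimate], title: str = "") -> str:
    """Aligned-text effects table; ^a marks odds ratios, ^c mean differences."""
    lines = []
    if title:
        lines.append(title)
    header = f"{'Outcome':<26}{'n':>7}{'Effect size (95% CI)':>30}{'P value':>10}"
    lines.append(header)
    lines.append("-" * len(header))
    for e in estimates:
        tag = "^a" if e.scale == "odds-ratio" else "^c"
        eff = f"{e.point:.2f} ({e.ci_low:.2f} to {e.ci_high:.2f}){tag}"
        p = "<.001" if e.p_value < 0.001 else f"{e.p_value:.3f}"
        lines.append(f"{e.outcome:<26}{e.n_used:>7}{eff:>30}{p:>10}")
    lines.append("^a odds ratio (binary outcome); ^c mean difference (continuous outcome)")
    return "\n".join(lines) + "\n"
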