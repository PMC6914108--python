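"""Synthetic EHR-like cohort generator with known ground truth.

Emulates a primary-care cohort of patients aged 50+ in which registration
for a patient portal (the "treatment") is confounded with demographics:
younger, higher-income, white, commercially insured patients are more
likely to register. Outcomes are four binary preventive behaviors (flu
shot, blood-pressure test, lipid test, colorectal screen), two continuous
chronic measures (systolic blood pressure in mm Hg, LDL in mg/dL, missing
completely at random for a configurable fraction of patients) and two
binary chronic conditions (diabetes, hypertension). True treatment effects
are configurable, so downstream matching estimators can be tested for
bias, coverage and confounding correction against a known answer.

Two named scenarios ship as defaults:

``paper-like``
    confounded assignment; preventive-behavior odds ratios > 1
    (flu 1.5, blood-pressure 1.15, lipid 1.5, colorectal 1.0) and null
    chronic effects — the qualitative conclusion a portal study reports.
``global-null``
    the same confounded assignment with every true effect null — the
    scenario under which confidence intervals must cover the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import (
    BEHAVIOR_OUTCOMES,
    BINARY_CHRONIC_OUTCOMES,
    BINARY_COVARIATES,
    CONTINUOUS_OUTCOMES,
    NOMINAL_LEVELS,
    validate_cohort,
)

__all__ = ["SimParams", "SimTruth", "scenario", "generate_cohort", "SCENARIOS"]


class InvalidParameterError(ValueError):
    """Simulation parameters violate their invariants."""


# -- default marginal covariate distributions (plausibility choices for a
#    US urban academic-health-system cohort aged 50+) ------------------------
DEFAULT_COVARIATE_DISTRIBUTIONS: dict = {
    "age": {"mean": 65.0, "sd": 10.5, "min": 50.0},
    "income": {"mean": 68_000.0, "sd": 30_000.0},  # log-normal, >= 0
    "sex": {"female": 0.60, "male": 0.40},
    "race": {"white": 0.645, "black": 0.270, "hispanic": 0.018, "other": 0.067},
    "insurance": {"commercial": 0.525, "medicaid": 0.062, "medicare": 0.405, "none": 0.008},
    "prov_faculty": 0.325,
    "prov_physician": 0.760,
    "prov_male": 0.410,
}

#: treatment-assignment log-odds (confounded): age lowers, income raises,
#: non-white race and public/no insurance lower the odds of portal use.
CONFOUNDED_TREAT_COEFS: dict = {
    "intercept": 1.00,
    "age": -0.30,       # per SD of age
    "income": 0.35,     # per SD of income
    "sex=male": 0.00,
    "race=black": -0.90,
    "race=hispanic": -1.00,
    "race=other": -0.25,
    "insurance=medicaid": -1.10,
    "insurance=medicare": -0.55,
    "insurance=none": -0.60,
    "prov_faculty": 0.20,
    "prov_physician": -0.10,
    "prov_male": 0.02,
}

NULL_TREAT_COEFS: dict = {k: 0.0 for k in CONFOUNDED_TREAT_COEFS}

#: fixed outcome-model structure: (baseline, covariate log-odds or slopes).
#: Behaviors load positively on income and white race, so confounded
#: assignment biases the crude behavior estimates upward. Coefficients are
#: kept modest so the marginal odds ratio in a balanced sample stays within
#: a fraction of a percent of the generating conditional odds ratio
#: (noncollapsibility attenuation ~ coef-variance / 3 on the log scale).
_BEHAVIOR_BASELINES = {"flu": -0.20, "bp_test": 1.70, "ldl_test": 0.85, "crc_test": 0.00}
_BEHAVIOR_COVARIATE_COEFS = {"age": 0.05, "income": 0.25, "race=white": 0.40}
_CHRONIC_BINARY_MODELS = {
    "diabetes": {"baseline": -1.60, "age": 0.25, "income": -0.20},
    "hypertension": {"baseline": 0.00, "age": 0.45, "income": -0.10},
}
_CHRONIC_CONTINUOUS_MODELS = {
    "sbp": {"baseline": 130.0, "age": 3.5, "noise_sd": 15.0},
    "ldl": {"baseline": 112.0, "age": -1.5, "noise_sd": 30.0},
}

DEFAULT_MISSING_RATES = {"sbp": 0.18, "ldl": 0.46}

PAPER_LIKE_EFFECTS: dict = {
    "flu": math.log(1.5),
    "bp_test": math.log(1.15),
    "ldl_test": math.log(1.5),
    "crc_test": 0.0,
    "sbp": 0.0,
    "ldl": 0.0,
    "diabetes": 0.0,
    "hypertension": 0.0,
}
GLOBAL_NULL_EFFECTS: dict = {k: 0.0 for k in PAPER_LIKE_EFFECTS}


@dataclass(frozen=True)
class SimParams:
    """Generator parameters.

    ``treat_coefs`` are log-odds of treatment per standardized continuous
    covariate / per indicator; ``outcome_effects`` are true treatment
    effects (log odds ratio for binary outcomes, additive shift in native
    units for continuous ones).
    """

    n_patients: int = 10_000
    treat_coefs: dict = field(default_factory=lambda: dict(CONFOUNDED_TREAT_COEFS))
    outcome_effects: dict = field(default_factory=lambda: dict(PAPER_LIKE_EFFECTS))
    covariate_distributions: dict = field(
        default_factory=lambda: {k: (dict(v) if isinstance(v, dict) else v)
                                 for k, v in DEFAULT_COVARIATE_DISTRIBUTIONS.items()}
    )
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    seed: int = 0

    def validate(self) -> "SimParams":
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients >= 1):
            raise InvalidParameterError(f"n_patients must be >= 1, got {self.n_patients}")
        for name in list(NOMINAL_LEVELS) :
            probs = self.covariate_distributions[name]
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise InvalidParameterError(
                    f"category probabilities for {name!r} sum to {total}, not 1"
                )
            if any(p < 0 for p in probs.values()):
                raise InvalidParameterError(f"negative probability in {name!r}")
        for out, rate in self.missing_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise InvalidParameterError(f"missing rate for {out!r} outside [0, 1]")
        return self


@dataclass(frozen=True)
class SimTruth:
    """Ground truth recorded alongside a generated cohort."""

    true_effects: dict
    realized_treated_fraction: float
    treat_coefs: dict


SCENARIOS = {
    "paper-like": dict(treat_coefs=CONFOUNDED_TREAT_COEFS, outcome_effects=PAPER_LIKE_EFFECTS),
    "global-null": dict(treat_coefs=CONFOUNDED_TREAT_COEFS, outcome_effects=GLOBAL_NULL_EFFECTS),
}


def scenario(name: str, n_patients: int = 10_000, seed: int = 0, **overrides) -> SimParams:
    """Named parameter preset; ``overrides`` replace any SimParams field."""
    if name not in SCENARIOS:
        raise InvalidParameterError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    preset = SCENARIOS[name]
    params = SimParams(
        n_patients=n_patients,
        treat_coefs=dict(preset["treat_coefs"]),
        outcome_effects=dict(preset["outcome_effects"]),
        seed=seed,
    )
    return replace(params, **overrides) if overrides else params


def _draw_covariates(params: SimParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_patients
    dist = params.covariate_distributions
    age_d = dist["age"]
    # truncated normal via rejection keeps the mean/SD interpretation usable
    age = rng.normal(age_d["mean"], age_d["sd"], size=n)
    lo = age_d.get("min", -np.inf)
    while True:
        bad = age < lo
        if not bad.any():
            break
        age[bad] = rng.normal(age_d["mean"], age_d["sd"], size=int(bad.sum()))

    inc_d = dist["income"]
    sigma2 = math.log1p((inc_d["sd"] / inc_d["mean"]) ** 2)
    mu = math.log(inc_d["mean"]) - sigma2 / 2.0
    income = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)

    cols = {"age": age, "income": income}
    for name, levels in NOMINAL_LEVELS.items():
        probs = [dist[name][lev] for lev in levels]
        cols[name] = rng.choice(levels, size=n, p=np.asarray(probs) / np.sum(probs))
    for name in BINARY_COVARIATES:
        cols[name] = rng.binomial(1, dist[name], size=n)
    return pd.DataFrame(cols)


def _design_terms(cov: pd.DataFrame, params: SimParams) -> dict[str, np.ndarray]:
    """Standardized / indicator terms the generator's linear predictors use."""
    dist = params.covariate_distributions
    terms: dict[str, np.ndarray] = {
        "age": (cov["age"].to_numpy() - dist["age"]["mean"]) / dist["age"]["sd"],
        "income": (cov["income"].to_numpy() - dist["income"]["mean"]) / dist["income"]["sd"],
    }
    for name, levels in NOMINAL_LEVELS.items():
        for lev in levels:
            terms[f"{name}={lev}"] = (cov[name].to_numpy() == lev).astype(float)
    for name in BINARY_COVARIATES:
        terms[name] = cov[name].to_numpy().astype(float)
    return terms


def generate_cohort(params: SimParams) -> tuple[pd.DataFrame, SimTruth]:
    """Draw a cohort and its ground truth; deterministic in (params, seed)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    cov = _draw_covariates(params, rng)
    terms = _design_terms(cov, params)

    logit_t = np.full(params.n_patients, params.treat_coefs.get("intercept", 0.0))
    for name, coef in params.treat_coefs.items():
        if name == "intercept" or coef == 0.0:
            continue
        if name not in terms:
            raise InvalidParameterError(f"treat_coefs references unknown term {name!r}")
        logit_t = logit_t + coef * terms[name]
    treated = rng.binomial(1, _expit(logit_t))

    out = {}
    effects = params.outcome_effects
    for name in BEHAVIOR_OUTCOMES:
        lp = _BEHAVIOR_BASELINES[name] + effects.get(name, 0.0) * treated
        for term, coef in _BEHAVIOR_COVARIATE_COEFS.items():
            lp = lp + coef * terms[term]
        out[name] = rng.binomial(1, _expit(lp))
    for name, model in _CHRONIC_BINARY_MODELS.items():
        lp = model["baseline"] + effects.get(name, 0.0) * treated
        lp = lp + model["age"] * terms["age"] + model["income"] * terms["income"]
        out[name] = rng.binomial(1, _expit(lp))
    for name, model in _CHRONIC_CONTINUOUS_MODELS.items():
        vals = (
            model["baseline"]
            + model["age"] * terms["age"]
            + effects.get(name, 0.0) * treated
            + rng.normal(0.0, model["noise_sd"], size=params.n_patients)
        )
        rate = params.missing_rates.get(name, 0.0)
        if rate > 0:
            vals = np.where(rng.random(params.n_patients) < rate, np.nan, vals)
        out[name] = vals

    cohort = pd.DataFrame({"id": np.arange(params.n_patients), "treated": treated})
    cohort = pd.concat([cohort, cov, pd.DataFrame(out)], axis=1)
    validate_cohort(cohort)
    truth = SimTruth(
        true_effects=dict(effects),
        realized_treated_fraction=float(treated.mean()),
        treat_coefs=dict(params.treat_coefs),
    )
    return cohort, truth


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))
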