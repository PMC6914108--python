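from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from cardmatch.balance import assert_balance
from cardmatch.cardinality import (
    BalanceSpec,
    build_balance_program,
    greedy_caliper_baseline,
    solve_cardinality,
)
from cardmatch.cohort import NOMINAL_LEVELS, arm_indices
from cardmatch.propensity import fit_propensity
from cardmatch.simulate import generate_cohort, scenario
from conftest import random_instance

SIMPLE_SPEC = BalanceSpec(moment_covariates=["age"], fine_covariates=[])


def brute_force_cardinality(cohort, spec):
    """Exhaustive search over equal-size treated/control subset pairs."""
    t_idx, c_idx = arm_indices(cohort)
    sds = {
        cov: cohort[cov].std(ddof=1) for cov in spec.moment_covariates
    }
    for k in range(min(t_idx.size, c_idx.size), 0, -1):
        for ts in combinations(t_idx, k):
            for cs in combinations(c_idx, k):
                ok = True
                for cov in spec.moment_covariates:
                    x = cohort[cov].to_numpy(float)
                    if abs(x[list(ts)].mean() - x[list(cs)].mean()) > (
                        spec.moment_tolerance * sds[cov] + 1e-9
                    ):
                        ok = False
                        break
                if ok:
                    for cov in spec.fine_covariates:
                        v = cohort[cov].to_numpy()
                        levels = (
                            NOMINAL_LEVELS[cov] if cov in NOMINAL_LEVELS else [0, 1]
                        )
                        for lev in levels:
                            if (v[list(ts)] == lev).sum() != (v[list(cs)] == lev).sum():
                                ok = False
                                break
                        if not ok:
                            break
                if ok:
                    return k
    return 0


def _identical_arms(n_treated, n_control):
    base = random_instance(np.random.default_rng(0), 1, 1).iloc[[0]]
    rows = pd.concat([base] * (n_treated + n_control), ignore_index=True)
    rows["id"] = np.arange(len(rows))
    rows["treated"] = np.r_[np.ones(n_treated, int), np.zeros(n_control, int)]
    return rows


def test_identical_covariates_select_everyone():
    cohort = _identical_arms(2, 2)
    result = solve_cardinality(cohort, BalanceSpec())
    assert result.cardinality == 2
    assert result.solver_status == "optimal"


def test_identical_arms_of_unequal_size_match_the_smaller():
    cohort = _identical_arms(5, 7)
    result = solve_cardinality(cohort, BalanceSpec())
    assert result.cardinality == 5


def test_zero_tolerance_with_disjoint_values_matches_nothing():
    cohort = _identical_arms(1, 1)
    cohort.loc[0, "age"] = 0.0
    cohort.loc[1, "age"] = 1.0
    spec = BalanceSpec(moment_covariates=["age"], moment_tolerance=0.0,
                       fine_covariates=[])
    result = solve_cardinality(cohort, spec)
    assert result.cardinality == 0


def test_constraint_row_count_is_structural(small_cohort):
    cohort, _ = small_cohort
    spec = BalanceSpec()
    program = build_balance_program(cohort, spec)
    n_levels = sum(
        len(NOMINAL_LEVELS[c]) if c in NOMINAL_LEVELS else 2
        for c in spec.fine_covariates
    )
    assert program.n_constraint_rows == 1 + 2 * len(spec.moment_covariates) + n_levels


def test_one_covariate_optimum_equals_exhaustive_search():
    cohort = random_instance(np.random.default_rng(42), 6, 6)
    spec = BalanceSpec(moment_covariates=["age"], moment_tolerance=0.05,
                       fine_covariates=[])
    result = solve_cardinality(cohort, spec)
    assert result.cardinality == brute_force_cardinality(cohort, spec)


def test_relaxing_tolerance_never_decreases_cardinality():
    cohort = random_instance(np.random.default_rng(3), 8, 9)
    cards = []
    for tol in (0.01, 0.05, 0.2, 1.0):
        spec = BalanceSpec(moment_covariates=["age", "income"],
                           moment_tolerance=tol, fine_covariates=["sex"])
        cards.append(solve_cardinality(cohort, spec).cardinality)
    assert cards == sorted(cards)


def test_returned_selection_satisfies_its_own_balance_spec():
    cohort, _ = generate_cohort(scenario("paper-like", 1500, seed=21))
    spec = BalanceSpec()
    result = solve_cardinality(cohort, spec)
    assert result.cardinality > 0
    report = assert_balance(result.achieved_balance, spec,
                            reference_sd=result.reference_sd)
    assert report.passed, report.failures


def test_selected_sets_are_disjoint_and_correctly_armed(small_cohort):
    cohort, _ = small_cohort
    result = solve_cardinality(cohort, BalanceSpec())
    t_idx, c_idx = arm_indices(cohort)
    assert set(result.selected_treated) <= set(t_idx)
    assert set(result.selected_control) <= set(c_idx)
    assert result.selected_treated.size == result.selected_control.size


def test_cardinality_dominates_balance_feasible_greedy_baseline():
    """The ILP's selling point: no balance-feasible design matches more."""
    spec = BalanceSpec()
    wins = 0
    for seed in range(20):
        cohort, _ = generate_cohort(scenario("paper-like", 600, seed=300 + seed))
        fit = fit_propensity(cohort)
        g_t, g_c = greedy_caliper_baseline(cohort, fit.logit_scores)
        result = solve_cardinality(cohort, spec)
        if g_t.size:
            from cardmatch.balance import balance_table

            rows = balance_table(cohort, (g_t, g_c))
            greedy_ok = assert_balance(rows, spec).passed
        else:
            greedy_ok = False
        greedy_feasible = g_t.size if greedy_ok else 0
        assert result.cardinality >= greedy_feasible
        if result.cardinality > greedy_feasible:
            wins += 1
    assert wins >= 15  # strictly larger on most confounded cohorts
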