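from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardmatch.pairing import (
    DistanceMatrix,
    PairingConfig,
    apply_caliper,
    build_distance_matrix,
    min_cost_pairing,
    rank_transform,
    robust_mahalanobis,
)
from cardmatch.propensity import PropensityFit


def _fake_fit(logits):
    logits = np.asarray(logits, dtype=float)
    scores = 1 / (1 + np.exp(-logits))
    return PropensityFit(
        coefficients=np.zeros(1), scores=scores, logit_scores=logits,
        converged=True, covariate_names=["intercept"],
    )


class TestRankTransform:
    def test_strict_order_gives_integer_ranks(self):
        assert rank_transform(np.array([[10.0], [20.0], [30.0]])).ravel().tolist() == [1, 2, 3]

    def test_ties_share_the_midrank(self):
        assert rank_transform(np.array([[5.0], [5.0], [9.0]])).ravel().tolist() == [1.5, 1.5, 3]

    def test_monotone_transform_leaves_ranks_unchanged(self):
        x = np.array([[0.3], [2.0], [1.1], [5.0]])
        assert np.array_equal(rank_transform(x), rank_transform(np.exp(x)))


class TestRobustMahalanobis:
    def test_identical_covariates_have_zero_distance(self):
        ranks = rank_transform(np.array([[1.0, 4.0], [1.0, 4.0], [2.0, 1.0]]))
        D = robust_mahalanobis(ranks, np.array([0]), np.array([1, 2]))
        assert D.matrix[0, 0] == pytest.approx(0.0, abs=1e-8)

    def test_single_covariate_closed_form(self):
        ranks = rank_transform(np.array([[10.0], [20.0], [30.0], [25.0]]))
        D = robust_mahalanobis(ranks, np.array([0, 1]), np.array([2, 3]))
        sd = np.std(ranks[:, 0], ddof=1)
        expected = np.abs(ranks[[0, 1], 0][:, None] - ranks[[2, 3], 0][None, :]) / sd
        assert np.abs(D.matrix - expected).max() < 1e-6

    def test_three_by_three_matches_matrix_inverse_oracle(self):
        rng = np.random.default_rng(1)
        ranks = rank_transform(rng.normal(size=(6, 3)))
        t, c = np.array([0, 1, 2]), np.array([3, 4, 5])
        D = robust_mahalanobis(ranks, t, c)
        S = np.cov(ranks, rowvar=False)
        S = S + np.eye(3) * (1e-8 * np.trace(S) / 3)
        S_inv = np.linalg.inv(S)
        for i, ti in enumerate(t):
            for j, cj in enumerate(c):
                d = ranks[ti] - ranks[cj]
                assert D.matrix[i, j] == pytest.approx(
                    np.sqrt(d @ S_inv @ d), abs=1e-10
                )

    def test_constant_column_is_dropped(self):
        ranks = np.column_stack([np.ones(4), [1.0, 2.0, 3.0, 4.0]])
        D = robust_mahalanobis(ranks, np.array([0, 1]), np.array([2, 3]))
        assert np.isfinite(D.matrix).all()


class TestCaliper:
    def test_no_violations_leave_distances_unchanged(self):
        D = DistanceMatrix(np.ones((2, 2)), np.array([0, 1]), np.array([2, 3]))
        fit = _fake_fit([0.0, 0.01, 0.0, 0.01])
        out = apply_caliper(D, fit, width=5.0, penalty_scale=100.0)
        assert np.array_equal(out.matrix, D.matrix)

    def test_only_violating_entries_increase(self):
        D = DistanceMatrix(np.ones((2, 2)), np.array([0, 1]), np.array([2, 3]))
        fit = _fake_fit([0.0, 3.0, 0.0, 3.0])
        out = apply_caliper(D, fit, width=0.5, penalty_scale=10.0)
        assert out.matrix[0, 0] == 1.0 and out.matrix[1, 1] == 1.0
        assert out.matrix[0, 1] > 1.0 and out.matrix[1, 0] > 1.0

    def test_penalty_is_linear_in_scale(self):
        D = DistanceMatrix(np.ones((2, 2)), np.array([0, 1]), np.array([2, 3]))
        fit = _fake_fit([0.0, 3.0, 0.0, 3.0])
        one = apply_caliper(D, fit, width=0.5, penalty_scale=10.0)
        two = apply_caliper(D, fit, width=0.5, penalty_scale=20.0)
        assert np.allclose(two.matrix - D.matrix, 2 * (one.matrix - D.matrix))


class TestMinCostPairing:
    def _dm(self, M):
        M = np.asarray(M, dtype=float)
        return DistanceMatrix(M, np.arange(M.shape[0]), np.arange(M.shape[1]))

    def test_obvious_diagonal_optimum(self):
        pairs = min_cost_pairing(self._dm([[1, 10], [10, 1]]))
        assert pairs.total_distance == 2.0
        assert sorted(pairs.pairs) == [(0, 0), (1, 1)]

    def test_greedy_trap_is_avoided(self):
        # greedy takes D[0,0]=1 then is stuck with 100; optimum crosses for 3
        pairs = min_cost_pairing(self._dm([[1, 2], [1, 100]]))
        assert pairs.total_distance == 3.0

    def test_matches_permutation_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            M = rng.uniform(0, 10, size=(5, 5))
            best = min(
                sum(M[i, p[i]] for i in range(5)) for p in permutations(range(5))
            )
            assert min_cost_pairing(self._dm(M)).total_distance == pytest.approx(best)

    def test_transposing_gives_the_same_total(self):
        rng = np.random.default_rng(8)
        M = rng.uniform(0, 5, size=(6, 6))
        assert min_cost_pairing(self._dm(M)).total_distance == pytest.approx(
            min_cost_pairing(self._dm(M.T)).total_distance
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_never_beaten_by_random_pairings(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        M = rng.uniform(0, 10, size=(n, n))
        opt = min_cost_pairing(self._dm(M)).total_distance
        for _ in range(100):
            perm = rng.permutation(n)
            assert opt <= M[np.arange(n), perm].sum() + 1e-9

    def test_non_square_matrix_is_rejected(self):
        with pytest.raises(ValueError, match="square"):
            min_cost_pairing(self._dm(np.ones((2, 3))))


def test_caliper_reduces_within_pair_propensity_gaps():
    """Penalized pairing yields closer propensity scores than unpenalized."""
    from cardmatch.cardinality import solve_cardinality
    from cardmatch.propensity import fit_propensity
    from cardmatch.simulate import generate_cohort, scenario

    better = 0
    for seed in range(20):
        cohort, _ = generate_cohort(scenario("paper-like", 300, seed=600 + seed))
        fit = fit_propensity(cohort)
        match = solve_cardinality(cohort)
        if match.cardinality == 0:
            continue
        gaps = {}
        for width, scale in ((0.2, None), (1e9, 0.0)):
            D = build_distance_matrix(
                cohort, match.selected_treated, match.selected_control, fit,
                PairingConfig(caliper_width=width, penalty_scale=scale),
            )
            pairs = min_cost_pairing(D)
            gaps[width] = np.mean(
                [abs(fit.scores[t] - fit.scores[c]) for t, c in pairs.pairs]
            )
        if gaps[0.2] <= gaps[1e9] + 1e-12:
            better += 1
    assert better >= 16
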