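"""AHP weighting: validation, aggregation, weights, lambda_max, consistency."""

import numpy as np
import pytest

from _oracles import (
    power_iteration_weights,
    principal_eigenvalue,
    random_reciprocal_pcm,
    random_saaty_weights,
)
from dietmcda.ahp import (
    DEFAULT_RI_TABLE,
    ConsistencyError,
    PairwiseComparisonMatrix,
    PCMValidationError,
    WeightVector,
    aggregate_expert_matrices,
    ahp_weights,
    consistency,
    derive_weights,
    lambda_max,
    validate_pcm,
)
from dietmcda.synthetic_data import gen_consistent_pcm, gen_noisy_pcm


class TestValidatePCM:
    def test_all_ones_matrix_is_valid(self):
        pcm = PairwiseComparisonMatrix(list("abc"), np.ones((3, 3)))
        assert validate_pcm(pcm) is pcm

    @pytest.mark.parametrize(
        "values, fragment",
        [
            ([[1, 3], [0.5, 1]], "reciprocity"),
            ([[1, 10], [0.1, 1]], "Saaty scale"),
            ([[2, 3], [1 / 3, 1]], "diagonal"),
            ([[1, -3], [-1 / 3, 1]], "non-positive"),
        ],
    )
    def test_broken_invariants_are_named(self, values, fragment):
        pcm = PairwiseComparisonMatrix(["a", "b"], values)
        with pytest.raises(PCMValidationError, match=fragment):
            validate_pcm(pcm)

    def test_non_square_rejected(self):
        pcm = PairwiseComparisonMatrix(["a", "b"], np.ones((2, 3)))
        with pytest.raises(PCMValidationError, match="2x2"):
            validate_pcm(pcm)


class TestAggregateExperts:
    def test_single_and_identical_matrices_are_fixed_points(self, simple_weights):
        pcm = gen_consistent_pcm(simple_weights)
        for group in ([pcm], [pcm, pcm]):
            agg = aggregate_expert_matrices(group)
            np.testing.assert_allclose(agg.values, pcm.values, rtol=1e-12)

    def test_geometric_mean_of_opposite_judgments_is_one(self):
        a = PairwiseComparisonMatrix(["a", "b"], [[1, 3], [1 / 3, 1]])
        b = PairwiseComparisonMatrix(["a", "b"], [[1, 1 / 3], [3, 1]])
        agg = aggregate_expert_matrices([a, b])
        np.testing.assert_allclose(agg.values, np.ones((2, 2)), atol=1e-12)

    def test_aggregate_preserves_reciprocity_and_scale(self, rng):
        mats = [
            PairwiseComparisonMatrix(list("abcd"), random_reciprocal_pcm(4, rng))
            for _ in range(5)
        ]
        agg = aggregate_expert_matrices(mats)
        validate_pcm(agg)

    def test_mismatched_criteria_rejected(self, simple_weights):
        pcm = gen_consistent_pcm(simple_weights)
        other = PairwiseComparisonMatrix(list("xyz"), pcm.values)
        with pytest.raises(ValueError, match="criteria"):
            aggregate_expert_matrices([pcm, other])


class TestDeriveWeights:
    def test_uniform_for_all_ones(self):
        pcm = PairwiseComparisonMatrix(list("abcd"), np.ones((4, 4)))
        np.testing.assert_allclose(derive_weights(pcm).weights, 0.25, rtol=1e-12)

    def test_two_by_two_hand_result(self):
        # column normalization of [[1,3],[1/3,1]]: both columns (3/4, 1/4)
        pcm = PairwiseComparisonMatrix(["a", "b"], [[1, 3], [1 / 3, 1]])
        np.testing.assert_allclose(derive_weights(pcm).weights, [0.75, 0.25], rtol=1e-12)

    def test_consistent_matrix_recovers_generating_weights(self, simple_weights):
        pcm = gen_consistent_pcm(simple_weights)
        w = derive_weights(pcm).weights
        assert np.max(np.abs(w - simple_weights.weights)) <= 1e-12

    def test_recovery_over_many_random_consistent_matrices(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 9))
            target = random_saaty_weights(n, rng)
            pcm = gen_consistent_pcm(WeightVector([f"c{i}" for i in range(n)], target))
            w = derive_weights(pcm).weights
            assert np.max(np.abs(w - target)) <= 1e-12

    def test_label_equivariance_under_permutation(self, rng):
        pcm = PairwiseComparisonMatrix(list("abcde"), random_reciprocal_pcm(5, rng))
        w = derive_weights(pcm)
        perm = ["c", "e", "a", "b", "d"]
        w_perm = derive_weights(pcm.reordered(perm))
        np.testing.assert_allclose(
            w_perm.weights, [w.as_dict()[c] for c in perm], rtol=1e-12
        )


class TestLambdaMax:
    def test_equals_n_for_all_ones(self):
        pcm = PairwiseComparisonMatrix(list("abcd"), np.ones((4, 4)))
        assert lambda_max(pcm, derive_weights(pcm)) == pytest.approx(4, abs=1e-12)

    def test_two_by_two_always_consistent(self, rng):
        for _ in range(50):
            x = float(np.exp(rng.uniform(np.log(1 / 9), np.log(9))))
            pcm = PairwiseComparisonMatrix(["a", "b"], [[1, x], [1 / x, 1]])
            assert lambda_max(pcm, derive_weights(pcm)) == pytest.approx(2, abs=1e-9)

    def test_cyclic_matrix_frozen_value(self, cyclic_pcm):
        # hand oracle: all column sums are 13/3, so AM weights are uniform
        # and every ratio (Mw)_i/w_i equals 13/3
        w = derive_weights(cyclic_pcm)
        np.testing.assert_allclose(w.weights, 1 / 3, rtol=1e-12)
        assert lambda_max(cyclic_pcm, w) == pytest.approx(13 / 3, abs=1e-12)

    def test_saaty_lower_bound_on_random_matrices(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 8))
            pcm = PairwiseComparisonMatrix(
                [f"c{i}" for i in range(n)], random_reciprocal_pcm(n, rng)
            )
            assert lambda_max(pcm, derive_weights(pcm)) >= n - 1e-9

    def test_matches_principal_eigenvalue_when_consistent(self, simple_weights):
        pcm = gen_consistent_pcm(simple_weights)
        lam = lambda_max(pcm, derive_weights(pcm))
        assert lam == pytest.approx(principal_eigenvalue(pcm.values), abs=1e-9)


class TestConsistency:
    def test_consistent_matrix_report(self, simple_weights):
        pcm = gen_consistent_pcm(simple_weights)
        rep = consistency(pcm, derive_weights(pcm))
        assert rep.ci == pytest.approx(0, abs=1e-12)
        assert rep.cr == pytest.approx(0, abs=1e-12)
        assert rep.passed

    def test_ci_formula_at_n_11(self):
        # inverting the reported CI: lambda_max 12.4 at n=11 gives CI 0.14
        assert (12.4 - 11) / (11 - 1) == pytest.approx(0.14, abs=1e-12)
        assert DEFAULT_RI_TABLE[11] == 1.51

    def test_unsupported_order_lists_sizes(self, rng):
        pcm = PairwiseComparisonMatrix(
            [f"c{i}" for i in range(16)],
            np.ones((16, 16)),
        )
        with pytest.raises(ValueError, match="supported sizes"):
            consistency(pcm, derive_weights(pcm))

    def test_strict_threshold_boundary(self, simple_weights, rng):
        pcm, info = gen_noisy_pcm(simple_weights, 0.5, (0.1, 0.25), seed=11)
        rep = consistency(pcm, derive_weights(pcm))
        assert not rep.passed
        assert rep.cr >= 0.1


class TestAhpWeights:
    def test_single_consistent_matrix_pipeline(self, simple_weights):
        pcm = gen_consistent_pcm(simple_weights)
        w, rep = ahp_weights([pcm])
        np.testing.assert_allclose(w.weights, simple_weights.weights, atol=1e-12)
        assert rep.cr == pytest.approx(0, abs=1e-12)

    def test_inconsistent_judgments_rejected_with_report(self, simple_weights):
        pcm, info = gen_noisy_pcm(simple_weights, 0.6, (0.12, 0.29), seed=3)
        with pytest.raises(ConsistencyError, match="consistency ratio") as exc:
            ahp_weights([pcm], enforce_cr=True)
        assert exc.value.report.cr >= 0.1
        w, rep = ahp_weights([pcm], enforce_cr=False)
        assert not rep.passed

    def test_two_expert_aggregate_lies_between_individuals(self, simple_weights):
        clean = gen_consistent_pcm(simple_weights)
        noisy, _ = gen_noisy_pcm(simple_weights, 0.15, (0.0, 0.1), seed=7)
        w_clean = derive_weights(clean).weights
        w_noisy = derive_weights(noisy).weights
        w_group, rep = ahp_weights([clean, noisy])
        assert rep.cr < 0.1
        lo = np.minimum(w_clean, w_noisy) - 5e-3
        hi = np.maximum(w_clean, w_noisy) + 5e-3
        assert np.all(w_group.weights >= lo) and np.all(w_group.weights <= hi)

    def test_arithmetic_mean_close_to_eigenvector_when_consistent_enough(self, rng):
        checked = 0
        for seed in range(200):
            n = 5
            target = random_saaty_weights(n, rng)
            wv = WeightVector([f"c{i}" for i in range(n)], target)
            pcm, info = gen_noisy_pcm(wv, 0.15, (0.0, 0.1), seed=seed, max_tries=50)
            w_am = derive_weights(pcm).weights
            w_ev = power_iteration_weights(pcm.values)
            assert np.max(np.abs(w_am - w_ev)) <= 0.02
            checked += 1
        assert checked == 200
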