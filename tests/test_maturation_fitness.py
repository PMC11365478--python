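"""Expression dynamics, attractor classification and the fitness function."""

import math

import numpy as np
import pytest

from evonet.maturation_fitness import (
    FREE,
    OptimumSpec,
    Outcome,
    evaluate_individual,
    fitness,
    mature,
    step_expression,
)

# 2-gene oscillator: mutual activation with stronger self-repression
OSCILLATOR = np.array([[-1.0, 0.5], [0.5, -1.0]])


def brute_force_mature(matrix, initial, step_cap=10_000):
    """Independent oracle: store the whole trajectory and scan for repeats."""
    trajectory = [np.asarray(initial, dtype=np.int8)]
    for _ in range(step_cap):
        nxt = step_expression(matrix, trajectory[-1])
        for first, past in enumerate(trajectory):
            if np.array_equal(past, nxt):
                period = len(trajectory) - first
                if period == 1:
                    return ("fixed_point", nxt, 1)
                return ("cycle", trajectory[first:], period)
        trajectory.append(nxt)
    return ("non_viable", None, 0)


class TestStepExpression:
    def test_zero_matrix_shuts_everything_off(self, rng):
        M = np.zeros((6, 6))
        state = rng.integers(0, 2, 6).astype(np.int8)
        assert not step_expression(M, state).any()

    def test_mutual_activators_sustain_expression(self):
        M = np.array([[0, 29 / 30], [29 / 30, 0]])
        np.testing.assert_array_equal(step_expression(M, [1, 1]), [1, 1])

    def test_oscillator_alternates(self):
        np.testing.assert_array_equal(step_expression(OSCILLATOR, [1, 0]), [0, 1])
        np.testing.assert_array_equal(step_expression(OSCILLATOR, [0, 1]), [1, 0])

    def test_strictly_positive_input_required(self):
        # net-zero and negative inputs both switch the gene off
        M = np.array([[1.0, -1.0], [0.0, -0.5]])
        np.testing.assert_array_equal(step_expression(M, [1, 1]), [0, 0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            step_expression(np.zeros((3, 3)), np.zeros(4, dtype=np.int8))


class TestMature:
    def test_zero_matrix_fixed_point_at_all_off(self):
        res = mature(np.zeros((10, 10)), np.ones(10, dtype=np.int8))
        assert res.outcome is Outcome.FIXED_POINT
        assert not res.final_state.any()
        assert res.period == 1

    def test_all_off_start_is_immediate_fixed_point(self):
        res = mature(np.zeros((4, 4)), np.zeros(4, dtype=np.int8))
        assert res.outcome is Outcome.FIXED_POINT
        assert res.steps_taken == 1

    def test_oscillator_cycle_period_two(self):
        res = mature(OSCILLATOR, np.array([1, 0], dtype=np.int8))
        assert res.outcome is Outcome.CYCLE
        assert res.period == 2
        states = {tuple(s) for s in res.cycle_states}
        assert states == {(1, 0), (0, 1)}

    def test_cycle_states_step_into_each_other(self):
        res = mature(OSCILLATOR, np.array([1, 0], dtype=np.int8))
        k = res.period
        for m in range(k):
            np.testing.assert_array_equal(
                step_expression(OSCILLATOR, res.cycle_states[m]),
                res.cycle_states[(m + 1) % k],
            )

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_agrees_with_brute_force_oracle(self, rng, n):
        """Outcome class, fixed point and period match a trajectory-scanning
        oracle on random matrices over all start states."""
        for _ in range(60):
            M = np.round(rng.uniform(-1, 1, (n, n)), 3)
            for bits in range(2**n):
                start = np.array([(bits >> k) & 1 for k in range(n)], dtype=np.int8)
                res = mature(M, start)
                kind, payload, period = brute_force_mature(M, start)
                assert res.outcome.value == kind
                assert res.period == period or kind == "non_viable"
                if kind == "fixed_point":
                    np.testing.assert_array_equal(res.final_state, payload)
                elif kind == "cycle":
                    got = {s.tobytes() for s in res.cycle_states}
                    want = {s.tobytes() for s in payload}
                    assert got == want

    def test_repeat_always_found_within_state_space_size(self, rng):
        """Pigeonhole: with step_cap > 2^n the outcome is never non-viable."""
        for _ in range(25):
            M = rng.uniform(-1, 1, (8, 8))
            start = rng.integers(0, 2, 8).astype(np.int8)
            assert mature(M, start, step_cap=300).outcome is not Outcome.NON_VIABLE

    def test_non_viable_when_cap_too_small(self):
        # from (1, 1) the oscillator needs 2 steps to reveal its fixed point
        res = mature(OSCILLATOR, np.array([1, 1], dtype=np.int8), step_cap=1)
        assert res.outcome is Outcome.NON_VIABLE
        assert res.steps_taken == 1


class TestFitness:
    def test_perfect_match_scores_one(self):
        opt = OptimumSpec.all_ones(10)
        assert fitness(np.ones(10, dtype=np.int8), opt) == 1.0

    def test_closed_form_for_full_mismatch(self):
        opt = OptimumSpec.all_ones(10, sigma2=5.0)
        expected = math.exp(-math.sqrt(10) / 5)
        assert fitness(np.zeros(10, dtype=np.int8), opt) == pytest.approx(expected)

    def test_eight_of_ten_mismatches_hits_plateau_level(self):
        """Two genes on out of ten gives the familiar 0.5680 plateau."""
        opt = OptimumSpec.all_ones(10, sigma2=5.0)
        expr = np.array([1, 1] + [0] * 8, dtype=np.int8)
        assert fitness(expr, opt) == pytest.approx(math.exp(-math.sqrt(8) / 5))
        assert round(fitness(expr, opt), 4) == 0.5680

    def test_free_genes_do_not_enter_distance(self):
        target = np.array([1, 1, FREE, FREE], dtype=np.int8)
        opt = OptimumSpec(target, sigma2=5.0)
        assert fitness(np.array([1, 1, 0, 1]), opt) == 1.0
        assert fitness(np.array([0, 1, 1, 1]), opt) == pytest.approx(math.exp(-1 / 5))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fitness(np.zeros(3), OptimumSpec.all_ones(4))

    def test_optimum_validation(self):
        with pytest.raises(ValueError):
            OptimumSpec(np.array([FREE, FREE]))
        with pytest.raises(ValueError):
            OptimumSpec(np.array([1, 0]), sigma2=0.0)


class TestEvaluateIndividual:
    def test_zero_matrix_generation_zero_fitness(self):
        opt = OptimumSpec.all_ones(10, sigma2=5.0)
        fit, res = evaluate_individual(np.zeros((10, 10)), np.ones(10, dtype=np.int8), opt)
        assert res.outcome is Outcome.FIXED_POINT
        assert fit == pytest.approx(math.exp(-math.sqrt(10) / 5))

    def test_cycle_scores_minimum_over_period(self):
        opt = OptimumSpec(np.array([1, 0], dtype=np.int8), sigma2=5.0)
        # cycle {(1,0), (0,1)}: fitnesses 1 and exp(-sqrt(2)/5)
        fit, res = evaluate_individual(OSCILLATOR, np.array([1, 0], dtype=np.int8), opt)
        assert res.outcome is Outcome.CYCLE
        assert fit == pytest.approx(math.exp(-math.sqrt(2) / 5))

    def test_non_viable_scores_zero(self):
        fit, res = evaluate_individual(
            OSCILLATOR, np.array([1, 1], dtype=np.int8),
            OptimumSpec.all_ones(2), step_cap=1,
        )
        assert res.outcome is Outcome.NON_VIABLE
        assert fit == 0.0

    def test_viable_fitness_strictly_positive(self, rng):
        opt = OptimumSpec.all_ones(5)
        for _ in range(50):
            M = rng.uniform(-1, 1, (5, 5))
            fit, res = evaluate_individual(M, np.ones(5, dtype=np.int8), opt)
            assert (fit > 0) == (res.outcome is not Outcome.NON_VIABLE)
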