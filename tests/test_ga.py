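"""Genetic-algorithm crossover, mutation and temperature minimization."""

import numpy as np
import pytest

from nestmax import (
    GAConfig,
    NestedSpec,
    brute_force_min_temperature,
    ga_crossover,
    ga_minimize,
    ga_mutate,
    perfect_nested,
    random_matrix,
)


class _RiggedRng:
    """Deterministic stand-in driving the crossover branch and k draw."""

    def __init__(self, uniform=0.9, k=2):
        self.uniform, self.k = uniform, k

    def random(self):
        return self.uniform

    def integers(self, lo, hi=None):
        return self.k


class TestCrossover:
    def test_copy_branch_returns_w(self):
        rng = _RiggedRng(uniform=0.1)
        w, p = np.array([3, 1, 2]), np.array([1, 2, 3])
        assert ga_crossover(w, p, rng).tolist() == [3, 1, 2]

    def test_k_equals_n_copies_w(self):
        rng = _RiggedRng(uniform=0.9, k=4)
        w, p = np.array([2, 4, 1, 3]), np.array([1, 2, 3, 4])
        assert ga_crossover(w, p, rng).tolist() == [2, 4, 1, 3]

    def test_identical_parents_reproduce_for_any_k(self):
        w = np.array([2, 3, 1, 4])
        for k in range(1, 5):
            assert ga_crossover(w, w.copy(), _RiggedRng(0.9, k)).tolist() == w.tolist()

    def test_worked_trace_with_repair(self):
        # w=(1,2,3,4), p=(4,3,2,1), k=2: p3=2 and p4=1 are already in {w1,w2},
        # so both open slots are repaired with the unused values {3,4} in order
        o = ga_crossover(np.array([1, 2, 3, 4]), np.array([4, 3, 2, 1]), _RiggedRng(0.9, 2))
        assert o.tolist() == [1, 2, 3, 4]

    def test_partner_elements_adopted_when_unused(self):
        # w=(1,2,3,4), p=(2,1,4,3), k=2: p3=4 and p4=3 are not in {w1,w2},
        # so both are copied straight from the partner
        o = ga_crossover(np.array([1, 2, 3, 4]), np.array([2, 1, 4, 3]), _RiggedRng(0.9, 2))
        assert o.tolist() == [1, 2, 4, 3]

    def test_offspring_always_a_permutation(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 12))
            w = rng.permutation(n) + 1
            p = rng.permutation(n) + 1
            o = ga_crossover(w, p, rng)
            assert sorted(o.tolist()) == list(range(1, n + 1))

    def test_length_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="length"):
            ga_crossover(np.array([1, 2]), np.array([1, 2, 3]), rng)


class TestMutation:
    def test_zero_probability_is_identity(self, rng):
        o = np.array([3, 1, 2])
        assert ga_mutate(o, 0.0, rng).tolist() == [3, 1, 2]

    def test_full_slice_rotation(self):
        class _R:
            def random(self):
                return 0.0

            def choice(self, n, size, replace):
                return np.array([0, n - 1])

        assert ga_mutate(np.array([1, 2, 3]), 1.0, _R()).tolist() == [3, 1, 2]

    def test_mutation_rate_is_binomial(self, rng):
        hits = 0
        base = np.arange(1, 7)
        for _ in range(10_000):
            if ga_mutate(base, 0.1, rng).tolist() != base.tolist():
                hits += 1
        # 1000 +/- 3 sigma with sigma = sqrt(1e4 * 0.1 * 0.9) = 30
        assert 910 <= hits <= 1090

    def test_result_remains_permutation(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 10))
            o = ga_mutate(rng.permutation(n) + 1, 1.0, rng)
            assert sorted(o.tolist()) == list(range(1, n + 1))


class TestBruteForce:
    def test_nested_3x3_has_zero_minimum(self):
        m = perfect_nested(NestedSpec(3, 3, 0.5))
        _, t = brute_force_min_temperature(m)
        assert t == 0.0

    def test_matches_independent_exhaustive_loop(self, rng):
        """Double implementation: a plain re-loop over all ranking pairs."""
        import itertools

        from nestmax import Ranking, temperature

        m = random_matrix(4, 3, 0.5, seed=11)
        _, t_fast = brute_force_min_temperature(m)
        best = np.inf
        for rperm in itertools.permutations(range(1, 5)):
            for cperm in itertools.permutations(range(1, 4)):
                r = Ranking(np.array(rperm), np.array(cperm))
                best = min(best, temperature(m, r).T)
        assert t_fast == pytest.approx(best, abs=1e-12)

    def test_guard_rejects_large_matrices(self):
        m = random_matrix(10, 10, 0.3, seed=0)
        with pytest.raises(ValueError, match="guard"):
            brute_force_min_temperature(m)


class TestMinimize:
    def test_perfect_matrix_solved_at_generation_zero(self):
        m = perfect_nested(NestedSpec(10, 8, 0.3))
        result = ga_minimize(m, GAConfig(seed=0))
        assert result.temperature.T == 0.0
        assert result.history[0] == 0.0  # degree seed is already optimal

    def test_best_history_non_increasing(self):
        m = random_matrix(8, 6, 0.35, seed=2)
        result = ga_minimize(m, GAConfig(seed=3, max_generations=50))
        assert all(a >= b for a, b in zip(result.history, result.history[1:]))

    def test_reproducible_for_fixed_seed(self):
        m = random_matrix(7, 6, 0.4, seed=5)
        a = ga_minimize(m, GAConfig(seed=42, max_generations=30))
        b = ga_minimize(m, GAConfig(seed=42, max_generations=30))
        assert a.history == b.history
        assert (a.ranking.row_order == b.ranking.row_order).all()
        assert (a.ranking.col_order == b.ranking.col_order).all()

    def test_attains_brute_force_optimum_on_small_matrices(self):
        for seed_m in (0, 1, 2):
            m = random_matrix(4, 4, 0.5, seed=seed_m)
            _, t_opt = brute_force_min_temperature(m)
            for seed in range(5):
                result = ga_minimize(m, GAConfig(seed=seed))
                assert result.temperature.T == pytest.approx(t_opt, abs=1e-9)

    def test_population_size_guard(self):
        with pytest.raises(ValueError, match="population_size"):
            GAConfig(population_size=1)
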