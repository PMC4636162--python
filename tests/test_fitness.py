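import math

import numpy as np
import pytest

from levyrisk.fitness import (
    encounter_probability_at,
    fitness_landscape,
    fitness_type1,
    fitness_type2,
    mean_search_time_approx,
    mean_search_time_exact,
    relative_fitness_type1,
    relative_fitness_type2,
)


def brute_force_mean_search_time(gamma: float, n: int) -> float:
    """Independent oracle: explicit geometric-law summation with the
    never-encountered survivor term, Kahan-compensated."""
    total = 0.0
    comp = 0.0
    for m in range(1, n + 1):
        term = m * (1.0 - gamma) ** (m - 1) * gamma
        y = term - comp
        t = total + y
        comp = (t - total) - y
        total = t
    return total + n * (1.0 - gamma) ** n


class TestEncounterProbability:
    @pytest.mark.parametrize("m, gamma, expected", [
        (1, 1.0, 1.0),
        (5, 0.0, 0.0),
        (3, 0.5, 0.125),
    ])
    def test_geometric_law(self, m, gamma, expected):
        assert encounter_probability_at(m, gamma) == pytest.approx(expected)

    def test_validates_domain(self):
        with pytest.raises(ValueError):
            encounter_probability_at(0, 0.5)
        with pytest.raises(ValueError):
            encounter_probability_at(1, 1.5)

    def test_probabilities_sum_with_survivor_term(self):
        gamma, n = 0.07, 200
        total = sum(encounter_probability_at(m, gamma) for m in range(1, n + 1))
        assert total + (1 - gamma) ** n == pytest.approx(1.0, abs=1e-12)


class TestMeanSearchTime:
    def test_certain_first_step_and_zero_limit(self):
        assert mean_search_time_exact(1.0, 50) == 1.0
        assert mean_search_time_exact(0.0, 50) == 50.0
        # tiny-gamma limit approaches n (the closed form loses a few digits
        # to cancellation there, which is fine at this scale)
        assert mean_search_time_exact(1e-12, 50) == pytest.approx(50.0, rel=1e-3)

    def test_small_example_against_hand_sum(self):
        # 1*0.5 + 2*0.25*0.5 + 2*0.25 = 1.5
        assert mean_search_time_exact(0.5, 2) == pytest.approx(1.5, abs=1e-15)

    def test_closed_form_equals_brute_force_summation(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            gamma = float(rng.uniform(1e-6, 1.0))
            n = int(rng.integers(1, 2000))
            exact = mean_search_time_exact(gamma, n)
            brute = brute_force_mean_search_time(gamma, n)
            assert abs(exact - brute) <= 1e-12 * max(1.0, abs(brute))

    def test_approximation_error_bounded_by_gamma(self):
        n = 10_000
        for gamma in (1e-5, 1e-4, 1e-3, 5e-3, 1e-2):
            k = gamma * n
            exact = mean_search_time_exact(gamma, n)
            approx = mean_search_time_approx(k, n)
            assert abs(approx - exact) / exact <= gamma

    def test_approx_examples_and_k_zero_limit(self):
        assert mean_search_time_approx(1.0, 10_000) == pytest.approx(
            10_000 * (1 - math.exp(-1)), rel=1e-12)
        assert mean_search_time_approx(0.0, 10_000) == 10_000.0
        # series branch continuous across the small-k switch
        assert mean_search_time_approx(1e-9, 100) == pytest.approx(
            mean_search_time_approx(2e-8, 100), rel=1e-6)


class TestFitness:
    def test_type1_example_and_linearity(self):
        phi = fitness_type1(eta=0.01, k=1.0, n=10_000, alpha=1.0)
        assert phi == pytest.approx(63.212, abs=0.001)
        assert fitness_type1(0.01, 1.0, 10_000, 2.0) == pytest.approx(2 * phi)
        assert fitness_type1(0.01, 0.0, 10_000, 1.0) == pytest.approx(100.0)

    def test_relative_type1_examples(self):
        assert relative_fitness_type1(0.5, 0.7, 0.5, 0.7) == 1.0
        got = relative_fitness_type1(2.0, 1.0, 1.0, 0.1)
        expected = 2.0 * 0.1 * (1 - math.exp(-1)) / (1.0 * (1 - math.exp(-0.1)))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.3285, abs=5e-4)

    def test_relative_type2_examples(self):
        assert relative_fitness_type2(0.3, 0.5, 0.1, 0.5) == pytest.approx(3.0)
        assert relative_fitness_type2(1.0, 1.5, 1.0, 0.5) == pytest.approx(
            math.exp(-1.0))
        # monotone decreasing in k_A
        ks = np.linspace(0, 5, 30)
        vals = relative_fitness_type2(1.0, ks, 1.0, 1.0)
        assert np.all(np.diff(vals) < 0)

    def test_ratio_requires_positive_denominator_rate(self):
        with pytest.raises(ValueError):
            relative_fitness_type1(1.0, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            relative_fitness_type2(1.0, 1.0, 0.0, 1.0)

    def test_ratio_of_absolute_fitnesses_is_independent_of_T_max(self):
        # the lifetime length n cancels exactly between numerator and
        # denominator, for both life cycles
        eta_a, k_a, eta_b, k_b = 0.013, 2.3, 0.006, 0.8
        for n in (100, 10_000, 1_000_000):
            r1 = fitness_type1(eta_a, k_a, n, 1.0) / fitness_type1(eta_b, k_b, n, 1.0)
            assert r1 == pytest.approx(
                relative_fitness_type1(eta_a, k_a, eta_b, k_b), rel=1e-12)
            r2 = fitness_type2(eta_a, k_a, n, 1.0) / fitness_type2(eta_b, k_b, n, 1.0)
            assert r2 == pytest.approx(
                relative_fitness_type2(eta_a, k_a, eta_b, k_b), rel=1e-12)

    def test_type2_penalizes_predation_at_least_as_much_as_type1(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            eta_a, eta_b = rng.uniform(0.001, 0.1, 2)
            k_b = rng.uniform(0.01, 5.0)
            k_a = k_b + rng.uniform(0.0, 5.0)  # focal suffers more predation
            r1 = relative_fitness_type1(eta_a, k_a, eta_b, k_b)
            r2 = relative_fitness_type2(eta_a, k_a, eta_b, k_b)
            assert r2 <= r1 + 1e-12


class TestLandscape:
    def test_identical_strategies_have_unit_ratio(self):
        for lc in ("I", "II"):
            df = fitness_landscape([1.0], [1.0], k_b=1.0, life_cycle=lc)
            assert df["phi_ratio"].iloc[0] == pytest.approx(1.0)

    def test_high_predation_type2_cell(self):
        # doubling the target rate does not rescue a strategy whose predator
        # exposure is 20% higher when k_b = 10
        df = fitness_landscape([2.0], [1.2], k_b=10.0, life_cycle="II")
        assert df["phi_ratio"].iloc[0] == pytest.approx(2 * math.exp(-2), rel=1e-9)
        assert df["phi_ratio"].iloc[0] < 1.0

    def test_surface_monotone_in_eta_ratio(self):
        eta = np.linspace(0.2, 3.0, 15)
        for lc in ("I", "II"):
            df = fitness_landscape(eta, [0.5, 1.0, 2.0], k_b=1.0, life_cycle=lc)
            for g, sub in df.groupby("gamma_ratio"):
                vals = sub.sort_values("eta_ratio")["phi_ratio"].to_numpy()
                assert np.all(np.diff(vals) > 0)

    def test_validates_inputs(self):
        with pytest.raises(ValueError):
            fitness_landscape([1.0], [1.0], k_b=0.0, life_cycle="I")
        with pytest.raises(ValueError):
            fitness_landscape([1.0], [1.0], k_b=1.0, life_cycle="III")
        with pytest.raises(ValueError):
            fitness_landscape([-1.0], [1.0], k_b=1.0, life_cycle="I")
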