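"""GA-PSO operations, bound assignment, exploration, and the PIO loop."""

import numpy as np
import pytest

from grnpio import (
    BoundsSet,
    DecoupledProblem,
    GeneParameters,
    PIOConfig,
    SensitivityConfig,
    SSystemNetwork,
    assign_bounds,
    exploration_phase,
    ga_step,
    init_population,
    pso_step,
    rank_and_split,
    run_pio,
    simulate_network,
)
from grnpio.optimizer import regenerate_population


class QuadraticProblem:
    """1-D convex stand-in objective: f(x) = x^2 on [-5, 5]."""

    n_params = 1
    lower = np.array([-5.0])
    upper = np.array([5.0])

    def evaluate(self, positions):
        positions = np.atleast_2d(positions)
        return positions[:, 0] ** 2

    def param_names(self):
        return ["x"]


def quad_bounds():
    return BoundsSet(lower=np.array([-5.0]), upper=np.array([5.0]),
                     velocity_bound=np.array([1.0]),
                     legal_lower=np.array([-5.0]), legal_upper=np.array([5.0]))


def decay_problem():
    net = SSystemNetwork([GeneParameters(0, 0.0, 1.0, np.zeros(1), np.ones(1))])
    observed = simulate_network(net, np.array([1.0]), n_steps=30, dt=0.1)
    return DecoupledProblem(observed, 0)


class TestInitPopulation:
    def test_within_bounds_and_gbest(self):
        problem = QuadraticProblem()
        pop = init_population(200, quad_bounds(), 0, problem)
        assert pop.size == 200
        assert np.all(pop.positions >= -5) and np.all(pop.positions <= 5)
        assert pop.gbest_fitness == pop.fitness.min()

    def test_seeded_determinism(self):
        problem = QuadraticProblem()
        a = init_population(50, quad_bounds(), 123, problem)
        b = init_population(50, quad_bounds(), 123, problem)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)


class TestRankAndSplit:
    def _pop(self, fitnesses):
        n = len(fitnesses)
        problem = QuadraticProblem()
        pop = init_population(n, quad_bounds(), 0, problem)
        pop.fitness = np.asarray(fitnesses, float)
        return pop

    def test_example_split(self):
        elite, pending = rank_and_split(self._pop([3.0, 1.0, 2.0, 4.0]), 0.5)
        assert sorted(elite.tolist()) == [1, 2]
        assert sorted(pending.tolist()) == [0, 3]

    def test_ceiling_rule_on_odd_population(self):
        elite, pending = rank_and_split(self._pop([5, 4, 3, 2, 1]), 0.5)
        assert len(elite) == 3 and len(pending) == 2

    def test_stable_tie_break_by_index(self):
        elite, _ = rank_and_split(self._pop([1.0] * 4), 0.5)
        assert elite.tolist() == [0, 1]


class TestPsoStep:
    def test_fixed_point_at_gbest(self):
        problem = QuadraticProblem()
        bounds = quad_bounds()
        pop = init_population(5, bounds, 1, problem)
        pop.positions[:] = pop.gbest_position
        pop.local_best_positions[:] = pop.gbest_position
        pop.velocities[:] = 0.0
        cfg = PIOConfig(inertia=0.0, seed=0)
        pso_step(pop, np.arange(5), bounds, cfg, 2, problem)
        assert np.allclose(pop.positions, pop.gbest_position)

    def test_gbest_never_increases(self):
        problem = QuadraticProblem()
        bounds = quad_bounds()
        pop = init_population(30, bounds, 3, problem)
        rng = np.random.default_rng(5)
        history = [pop.gbest_fitness]
        for _ in range(50):
            pso_step(pop, np.arange(30), bounds, PIOConfig(seed=0), rng, problem)
            history.append(pop.gbest_fitness)
        assert np.all(np.diff(history) <= 0)

    def test_quadratic_convergence(self):
        problem = QuadraticProblem()
        bounds = quad_bounds()
        pop = init_population(10, bounds, 7, problem)
        rng = np.random.default_rng(11)
        for _ in range(50):
            pso_step(pop, np.arange(10), bounds, PIOConfig(seed=0), rng, problem)
        assert abs(pop.gbest_position[0]) < 1e-2


class TestGaStep:
    def test_identical_parents_no_mutation_clone(self):
        problem = QuadraticProblem()
        bounds = quad_bounds()
        pop = init_population(4, bounds, 2, problem)
        pop.positions[:] = 1.5
        pop.fitness[:] = problem.evaluate(pop.positions)
        cfg = PIOConfig(mutation_rate=0.0, seed=0)
        ga_step(pop, np.array([2, 3]), bounds, cfg, 4, problem)
        assert np.allclose(pop.positions[[2, 3]], 1.5)

    def test_children_within_bounds(self):
        problem = QuadraticProblem()
        bounds = quad_bounds()
        pop = init_population(40, bounds, 6, problem)
        rng = np.random.default_rng(8)
        for _ in range(20):
            ga_step(pop, np.arange(20, 40), bounds, PIOConfig(seed=0), rng, problem)
            assert np.all(pop.positions >= bounds.lower - 1e-12)
            assert np.all(pop.positions <= bounds.upper + 1e-12)

    def test_tournament_favors_best(self):
        # P(best among [1,10,10,10] picked per parent draw) = 1-(3/4)^2 = 0.4375
        problem = QuadraticProblem()
        bounds = quad_bounds()
        pop = init_population(4, bounds, 0, problem)
        pop.fitness = np.array([1.0, 10.0, 10.0, 10.0])
        pop.positions[:, 0] = np.array([0.0, 1.0, 1.0, 1.0])
        rng = np.random.default_rng(99)
        n, hits = 10000, 0
        for _ in range(n):
            cand = rng.integers(0, 4, (1, 2))
            winner = cand[0, np.argmin(pop.fitness[cand[0]])]
            hits += winner == 0
        assert hits / n >= 0.40


class TestAssignBounds:
    def _bounds(self):
        lo = np.array([0.0, -3.0])
        hi = np.array([10.0, 3.0])
        return BoundsSet(lower=lo.copy(), upper=hi.copy(),
                         velocity_bound=np.array([0.5, 0.5]),
                         legal_lower=lo, legal_upper=hi)

    def test_tight_interval(self):
        new = assign_bounds(np.array([True, True]), np.array([1.0, 1.0]), self._bounds())
        assert new.lower[0] == pytest.approx(0.0)
        assert new.upper[0] == pytest.approx(2.0)

    def test_loose_interval_clipped_to_legal(self):
        new = assign_bounds(np.array([False, False]), np.array([1.0, 1.0]), self._bounds())
        assert new.lower[1] == pytest.approx(-1.5)
        assert new.upper[1] == pytest.approx(3.0)  # 3.5 clipped to legal

    def test_regenerated_values_inside_new_intervals(self):
        problem = QuadraticProblem()
        bounds = quad_bounds()
        pop = init_population(50, bounds, 0, problem)
        new = assign_bounds(np.array([True]), pop.gbest_position, bounds)
        regenerate_population(pop, new, 1, problem)
        assert np.all(pop.positions >= new.lower) and np.all(pop.positions <= new.upper)

    def test_collapsed_interval_widened(self):
        b = self._bounds()
        new = assign_bounds(np.array([True, True]), np.array([10.0, 3.0]),
                            BoundsSet(lower=b.lower, upper=b.upper,
                                      velocity_bound=np.array([1e-9, 1e-9]),
                                      legal_lower=b.legal_lower,
                                      legal_upper=b.legal_upper))
        assert np.all(new.upper - new.lower >= 1e-3 - 1e-12)


class TestExplorationPhase:
    def test_top_particles_untouched(self):
        problem = QuadraticProblem()
        bounds = quad_bounds()
        pop = init_population(200, bounds, 0, problem)
        order = np.argsort(pop.fitness, kind="stable")
        top2 = order[:2]
        before = pop.positions[top2].copy()
        exploration_phase(pop, bounds, 0.01, 1, problem)
        assert np.array_equal(pop.positions[top2], before)

    def test_gbest_never_worsens(self):
        problem = QuadraticProblem()
        bounds = quad_bounds()
        pop = init_population(50, bounds, 0, problem)
        before = pop.gbest_fitness
        exploration_phase(pop, bounds, 0.01, 2, problem)
        assert pop.gbest_fitness <= before

    def test_spread_restored_on_converged_population(self):
        problem = QuadraticProblem()
        bounds = quad_bounds()
        pop = init_population(100, bounds, 0, problem)
        pop.positions[:] = pop.gbest_position  # fully converged
        spread_before = pop.positions.std(axis=0)
        exploration_phase(pop, bounds, 0.01, 3, problem)
        assert np.all(pop.positions.std(axis=0) >= spread_before)


class TestRunPio:
    def test_gbest_history_monotone(self):
        res = run_pio(decay_problem(),
                      PIOConfig(max_gen=60, pop_size=40,
                                identification_interval=20,
                                exploration_interval=40, seed=4,
                                sensitivity=SensitivityConfig(n_samples=50)))
        assert np.all(np.diff(res.gbest_history) <= 0)
        assert res.phase_generations == [20, 40, 60]

    def test_decay_problem_reaches_low_mse(self):
        # ~5000 evaluations (pop 50 x 100 generations)
        res = run_pio(decay_problem(),
                      PIOConfig(max_gen=100, pop_size=50,
                                identification_interval=0,
                                exploration_interval=0, seed=0),
                      final_sensitivity=False)
        assert res.fitness < 1e-3

    def test_disabled_intervals_run_no_phases(self):
        res = run_pio(decay_problem(),
                      PIOConfig(max_gen=30, pop_size=20,
                                identification_interval=0,
                                exploration_interval=0, seed=1),
                      final_sensitivity=False)
        assert res.phase_generations == []
        assert res.final_report is None

    def test_deterministic_per_seed(self):
        cfg = PIOConfig(max_gen=25, pop_size=20, identification_interval=10,
                        exploration_interval=20, seed=77,
                        sensitivity=SensitivityConfig(n_samples=30))
        a = run_pio(decay_problem(), cfg, final_sensitivity=False)
        b = run_pio(decay_problem(), cfg, final_sensitivity=False)
        assert np.array_equal(a.gbest_history, b.gbest_history)
        assert np.array_equal(a.position, b.position)

    def test_positions_respect_bounds_through_random_operation_sequences(self):
        problem = decay_problem()
        bounds = BoundsSet.from_problem(problem)
        rng = np.random.default_rng(13)
        pop = init_population(30, bounds, rng, problem)
        cfg = PIOConfig(seed=0)
        for step in range(40):
            op = rng.integers(0, 4)
            before = pop.gbest_fitness
            if op == 0:
                elite, pending = rank_and_split(pop, 0.5)
                pso_step(pop, elite, bounds, cfg, rng, problem)
            elif op == 1:
                elite, pending = rank_and_split(pop, 0.5)
                ga_step(pop, pending, bounds, cfg, rng, problem)
            elif op == 2:
                exploration_phase(pop, bounds, 0.01, rng, problem)
            else:
                mask = rng.random(bounds.n_params) < 0.5
                bounds = assign_bounds(mask, pop.gbest_position, bounds)
                regenerate_population(pop, bounds, rng, problem)
            assert np.all(pop.positions >= bounds.lower - 1e-12)
            assert np.all(pop.positions <= bounds.upper + 1e-12)
            assert pop.gbest_fitness <= before + 1e-15
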