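import numpy as np
import pytest

from eagletune.bes import (
    BESConfig,
    EaglePopulation,
    compute_weight,
    compute_weights,
    greedy_update,
    optimize,
    search_positions,
    select_positions,
    swoop_positions,
    _normalize_by_max_abs,
)
from eagletune.benchmarks import sphere
from eagletune.chaos import ConfigurationError, SearchSpace


def make_pop(space, positions, fitnesses, p_best=None, g_best=None):
    pop = EaglePopulation(space=space, positions=np.array(positions, dtype=float))
    pop.fitnesses = np.array(fitnesses, dtype=float)
    best = int(np.argmin(pop.fitnesses))
    pop.p_best = np.array(p_best, dtype=float) if p_best is not None else pop.positions[best].copy()
    pop.g_best = float(g_best) if g_best is not None else float(pop.fitnesses[best])
    return pop


WIDE = SearchSpace(lower=(-100.0, -100.0), upper=(100.0, 100.0), scale=("linear", "linear"))


class TestSelectPhase:
    def test_hand_arithmetic(self, constant_rng):
        # Pbest=[0,0], Pmean=[1,1], P_0=[2,2], alpha=1.5, gamma=0.5
        pop = make_pop(WIDE, [[2.0, 2.0], [0.0, 0.0]], [5.0, 1.0])
        cfg = BESConfig(n_agents=2, max_iter=1, variant="bes", alpha=1.5)
        prop = select_positions(pop, cfg, constant_rng(0.5))
        assert np.allclose(prop[0], [-0.75, -0.75])
        assert np.allclose(prop[1], [0.75, 0.75])

    def test_gamma_zero_collapses_to_best(self, constant_rng):
        pop = make_pop(WIDE, [[2.0, 2.0], [0.0, 0.0]], [5.0, 1.0])
        cfg = BESConfig(n_agents=2, max_iter=1, variant="bes")
        prop = select_positions(pop, cfg, constant_rng(0.0))
        assert np.allclose(prop, np.tile(pop.p_best, (2, 1)))

    def test_degenerate_population_is_fixed_point(self, constant_rng):
        pop = make_pop(WIDE, [[3.0, 3.0], [3.0, 3.0]], [1.0, 1.0])
        cfg = BESConfig(n_agents=2, max_iter=1, variant="bes")
        prop = select_positions(pop, cfg, constant_rng(0.7))
        assert np.allclose(prop, pop.positions)

    def test_clipping_to_bounds(self, constant_rng):
        space = SearchSpace(lower=(0.0, 0.0), upper=(10.0, 10.0), scale=("linear", "linear"))
        pop = make_pop(space, [[2.0, 2.0], [0.0, 0.0]], [5.0, 1.0])
        cfg = BESConfig(n_agents=2, max_iter=1, variant="bes", alpha=1.5)
        prop = select_positions(pop, cfg, constant_rng(0.5))
        assert np.allclose(prop[0], [0.0, 0.0])  # -0.75 clipped up

    def test_mbes_requires_fuch_state(self, rng):
        pop = make_pop(WIDE, [[2.0, 2.0], [0.0, 0.0]], [5.0, 1.0])
        cfg = BESConfig(n_agents=2, max_iter=1, variant="mbes")
        with pytest.raises(ValueError, match="Fuch"):
            select_positions(pop, cfg, rng, fuch=None)

    def test_unevaluated_population_rejected(self, rng):
        pop = EaglePopulation(space=WIDE, positions=np.zeros((2, 2)))
        cfg = BESConfig(n_agents=2, max_iter=1, variant="bes")
        with pytest.raises(RuntimeError, match="evaluated"):
            select_positions(pop, cfg, rng)


class TestSearchPhase:
    def test_identical_population_is_fixed_point(self, rng):
        pop = make_pop(WIDE, [[1.5, -2.0], [1.5, -2.0]], [3.0, 3.0])
        cfg = BESConfig(n_agents=2, max_iter=1, variant="bes")
        prop = search_positions(pop, cfg, rng)
        assert np.allclose(prop, pop.positions)

    def test_proposals_respect_bounds(self, rng):
        space = SearchSpace(lower=(0.0, 0.0), upper=(1e-6, 1e-6), scale=("linear", "linear"))
        pop = make_pop(space, [[0.0, 1e-6], [5e-7, 0.0], [1e-6, 5e-7]], [3.0, 1.0, 2.0])
        cfg = BESConfig(n_agents=3, max_iter=1, variant="bes")
        for _ in range(20):
            prop = search_positions(pop, cfg, rng)
            assert (prop >= 0.0).all() and (prop <= 1e-6).all()

    def test_spiral_coefficients_normalized_to_unit_max(self, rng):
        v = rng.normal(size=40)
        x = _normalize_by_max_abs(v)
        assert np.max(np.abs(x)) == pytest.approx(1.0)

    def test_zero_vector_normalization_guard(self):
        assert np.array_equal(_normalize_by_max_abs(np.zeros(5)), np.zeros(5))


class TestSwoopPhase:
    def test_zero_weight_contracts_onto_best(self, constant_rng):
        pop = make_pop(WIDE, [[2.0, 2.0], [4.0, -4.0]], [5.0, 1.0], p_best=[4.0, -4.0])
        cfg = BESConfig(n_agents=2, max_iter=1, variant="mbes")
        prop = swoop_positions(pop, cfg, constant_rng(0.5), weights=np.zeros(2))
        assert np.allclose(prop, 0.5 * np.tile(pop.p_best, (2, 1)))

    def test_unit_weight_reproduces_plain_variant(self):
        pop1 = make_pop(WIDE, [[2.0, 2.0], [4.0, -4.0]], [5.0, 1.0])
        pop2 = make_pop(WIDE, [[2.0, 2.0], [4.0, -4.0]], [5.0, 1.0])
        cfg_b = BESConfig(n_agents=2, max_iter=1, variant="bes")
        cfg_m = BESConfig(n_agents=2, max_iter=1, variant="mbes")
        p1 = swoop_positions(pop1, cfg_b, np.random.default_rng(7))
        p2 = swoop_positions(pop2, cfg_m, np.random.default_rng(7), weights=np.ones(2))
        assert np.array_equal(p1, p2)

    def test_weights_contract_enforced(self, rng):
        pop = make_pop(WIDE, [[2.0, 2.0], [4.0, -4.0]], [5.0, 1.0])
        with pytest.raises(ValueError, match="weights"):
            swoop_positions(pop, BESConfig(n_agents=2, max_iter=1, variant="mbes"), rng, weights=None)
        with pytest.raises(ValueError, match="weights"):
            swoop_positions(pop, BESConfig(n_agents=2, max_iter=1, variant="bes"), rng, weights=np.ones(2))


class TestAdaptiveWeight:
    @pytest.mark.parametrize(
        "fit_i, avg, best, t, T, expected",
        [
            (3.0, 5.0, 1.0, 10, 10, 0.9),  # final iteration: cos(0)
            (7.0, 5.0, 1.0, 10, 10, 0.9),  # final iteration, poor eagle
            (1.0, 5.0, 1.0, 3, 10, 0.9),  # incumbent best: ratio 0
            (7.0, 5.0, 1.0, 0, 10, 0.0),  # worst case at t=0: cos(pi/2)
        ],
    )
    def test_limit_values(self, fit_i, avg, best, t, T, expected):
        assert compute_weight(fit_i, avg, best, t, T) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_population_gives_point_nine(self):
        assert compute_weight(2.0, 2.0, 2.0, 0, 10) == pytest.approx(0.9)

    def test_bounds_over_random_inputs(self, rng):
        for _ in range(2000):
            best = rng.normal()
            avg = best + abs(rng.normal())
            fit = best + abs(rng.normal()) * 2.0
            T = int(rng.integers(1, 200))
            t = int(rng.integers(0, T + 1))
            w = compute_weight(fit, avg, best, t, T)
            assert 0.0 <= w <= 0.9

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            compute_weight(1.0, 2.0, 0.0, 0, 0)

    def test_vectorized_ignores_nonfinite_in_average(self):
        fits = np.array([1.0, 2.0, np.inf])
        w = compute_weights(fits, 1.0, 5, 10)
        assert w.shape == (3,)
        assert np.all((w >= 0.0) & (w <= 0.9))


class TestGreedyUpdate:
    def test_single_improvement_scenario(self):
        # eagle 0 improves 5 -> 3, eagle 1 worsens 6 -> 7
        space = SearchSpace(lower=(0.0,), upper=(10.0,), scale=("linear",))
        pop = make_pop(space, [[5.0], [6.0]], [5.0, 6.0])
        objective = lambda x: float(x[0])
        greedy_update(pop, np.array([[3.0], [7.0]]), objective)
        assert np.allclose(pop.positions, [[3.0], [6.0]])
        assert pop.g_best == 3.0
        assert pop.evaluations == 2

    def test_all_worse_leaves_population_unchanged(self):
        space = SearchSpace(lower=(0.0,), upper=(10.0,), scale=("linear",))
        pop = make_pop(space, [[1.0], [2.0]], [1.0, 2.0])
        objective = lambda x: float(x[0])
        greedy_update(pop, np.array([[5.0], [6.0]]), objective)
        assert np.allclose(pop.positions, [[1.0], [2.0]])
        assert pop.g_best == 1.0

    def test_tie_keeps_incumbent(self):
        space = SearchSpace(lower=(0.0,), upper=(10.0,), scale=("linear",))
        pop = make_pop(space, [[1.0], [2.0]], [1.0, 2.0])
        greedy_update(pop, np.array([[1.0], [2.0]]), lambda x: float(x[0]))
        assert np.allclose(pop.positions, [[1.0], [2.0]])

    def test_nonfinite_objective_never_accepted(self):
        space = SearchSpace(lower=(-10.0,), upper=(10.0,), scale=("linear",))
        pop = make_pop(space, [[1.0], [2.0]], [1.0, 2.0])
        greedy_update(pop, np.array([[-5.0], [-6.0]]), lambda x: float("nan"))
        assert np.allclose(pop.positions, [[1.0], [2.0]])
        assert np.isfinite(pop.fitnesses).all()


class TestOptimize:
    def test_constant_objective_flat_trace(self, linear_space):
        cfg = BESConfig(n_agents=5, max_iter=10, variant="mbes")
        _, best, trace = optimize(lambda x: 4.2, linear_space, cfg, seed=0)
        assert best == 4.2
        assert np.all(trace.best_per_iter == 4.2)

    def test_same_seed_bit_identical(self, linear_space):
        cfg = BESConfig(n_agents=10, max_iter=15, variant="mbes")
        p1, f1, t1 = optimize(sphere, linear_space, cfg, seed=11)
        p2, f2, t2 = optimize(sphere, linear_space, cfg, seed=11)
        assert np.array_equal(p1, p2) and f1 == f2
        assert np.array_equal(t1.best_per_iter, t2.best_per_iter)

    def test_trace_monotone_and_budget_accounted(self, linear_space):
        cfg = BESConfig(n_agents=8, max_iter=20, variant="mbes")
        _, _, trace = optimize(sphere, linear_space, cfg, seed=2)
        assert np.all(np.diff(trace.best_per_iter) <= 0)
        assert trace.evaluations == 8 * (1 + 3 * 20)

    def test_sphere_converges_quickly(self, linear_space):
        cfg = BESConfig(n_agents=15, max_iter=40, variant="mbes")
        _, best, _ = optimize(sphere, linear_space, cfg, seed=4)
        assert best < 1e-3

    def test_variant_reduction_bit_for_bit(self, linear_space):
        cfg_b = BESConfig(n_agents=10, max_iter=20, variant="bes")
        cfg_m = BESConfig(
            n_agents=10, max_iter=20, variant="mbes",
            init_mode="uniform", gamma_source="uniform", weight_mode="one",
        )
        p1, f1, t1 = optimize(sphere, linear_space, cfg_b, seed=3)
        p2, f2, t2 = optimize(sphere, linear_space, cfg_m, seed=3)
        assert np.array_equal(p1, p2) and f1 == f2
        assert np.array_equal(t1.best_per_iter, t2.best_per_iter)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alpha=1.0),
            dict(angle_param=3.0),
            dict(cycle_param=0.1),
            dict(c1=0.5),
            dict(n_agents=1),
            dict(max_iter=0),
            dict(variant="pso"),
        ],
    )
    def test_out_of_range_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            BESConfig(**kwargs)

    def test_table_defaults(self):
        cfg = BESConfig()
        assert (cfg.alpha, cfg.angle_param, cfg.cycle_param) == (1.5, 10.0, 1.5)
        assert (cfg.c1, cfg.c2, cfg.n_agents, cfg.max_iter) == (2.0, 2.0, 100, 100)
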