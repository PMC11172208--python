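import numpy as np
import pytest

import fraccs.fractional_cuckoo as fcs_mod
from fraccs import (
    CaputoSpec,
    Nest,
    OptimizerConfig,
    Population,
    SearchBounds,
    cfo_global_step,
    cfo_local_step,
    exploration_reference,
    rank_population,
    run_cfo_cs,
    run_cs,
    sphere,
)
from fraccs.caputo import derivative_table
from fraccs.cuckoo import n_abandoned


class ForcedR:
    """rng stub returning fixed values for the three reference draws."""

    def __init__(self, value):
        self.value = value

    def uniform(self, low=0.0, high=1.0, size=None):
        return np.full(size, self.value) if size else self.value


def make_ranked_pop(positions, objective):
    pop = Population(nests=[Nest(position=np.asarray(p, float)) for p in positions])
    for nest in pop.nests:
        nest.set_fitness(objective(nest.position))
    return rank_population(pop)


class TestExplorationReference:
    def test_coincident_best_returns_nest_position(self, rng):
        x = np.array([0.4, 0.6])
        ck = exploration_reference(Nest(position=x), Nest(position=x.copy()), rng)
        assert np.allclose(ck, x)

    def test_zero_draws_return_nest_position(self):
        nest, best = Nest(position=np.array([0.0])), Nest(position=np.array([1.0]))
        assert np.allclose(exploration_reference(nest, best, ForcedR(0.0)), [0.0])

    def test_unit_draws_direct_arithmetic(self):
        nest, best = Nest(position=np.array([0.0])), Nest(position=np.array([1.0]))
        assert np.allclose(exploration_reference(nest, best, ForcedR(1.0)), [-1.0])


class TestCfoSteps:
    def test_flat_objective_keeps_position(self):
        config = OptimizerConfig(seed=0)
        bounds = SearchBounds.unit(2)
        spec = CaputoSpec(alpha=0.7, memory_terms=4, fd_step=0.01)
        flat = lambda x: 1.0
        nest = Nest(position=np.array([0.3, 0.6]))
        best = Nest(position=np.array([0.5, 0.5]))
        derivs = derivative_table(flat, best.position, 4, spec.fd_step)
        out = cfo_global_step(nest, best, derivs, config, spec, bounds, np.random.default_rng(0))
        assert np.array_equal(out, nest.position)

    def test_integer_order_reduction_is_plain_gradient_step(self, monkeypatch):
        # alpha=1, M=1, Levy forced to ones: step = beta * f'(x_best)
        monkeypatch.setattr(fcs_mod, "levy_step", lambda d, lam, rng: np.ones(d))
        config = OptimizerConfig(seed=0, alpha=1.0, memory_terms=1, beta=0.3)
        bounds = SearchBounds.cube(1, -10.0, 10.0)
        spec = CaputoSpec(alpha=1.0, memory_terms=1, fd_step=0.01)
        f = lambda x: float(x[0] ** 2)
        nest = Nest(position=np.array([1.0]))
        best = Nest(position=np.array([2.0]))
        derivs = derivative_table(f, best.position, 1, spec.fd_step)
        out = cfo_global_step(nest, best, derivs, config, spec, bounds, np.random.default_rng(0))
        assert out[0] == pytest.approx(1.0 + 0.3 * 4.0, abs=1e-8)

    def test_local_step_pa_zero_keeps_position(self):
        config = OptimizerConfig(seed=0, pa=0.0)
        bounds = SearchBounds.unit(2)
        spec = CaputoSpec(fd_step=0.01)
        f = lambda x: float(np.sum(x**2))
        pop = make_ranked_pop([[0.2, 0.2], [0.5, 0.5], [0.9, 0.9]], f)
        derivs = derivative_table(f, pop.best.position, 4, spec.fd_step)
        out = cfo_local_step(
            pop.nests[2], pop, pop.best, derivs, config, spec, bounds,
            np.random.default_rng(0),
        )
        assert np.array_equal(out, pop.nests[2].position)

    def test_local_step_degenerate_best_equals_worst(self):
        config = OptimizerConfig(seed=0, pa=1.0)
        bounds = SearchBounds.unit(2)
        spec = CaputoSpec(alpha=0.5, fd_step=0.01)
        f = lambda x: float(np.sum(x**2))
        pop = make_ranked_pop([[0.4, 0.4], [0.4, 0.4]], f)
        derivs = derivative_table(f, pop.best.position, 4, spec.fd_step)
        out = cfo_local_step(
            pop.nests[1], pop, pop.best, derivs, config, spec, bounds,
            np.random.default_rng(0),
        )
        assert np.allclose(out, pop.nests[1].position)

    def test_local_step_moves_only_masked_coordinates(self, monkeypatch):
        # force the mask by stubbing the per-coordinate uniform draws
        config = OptimizerConfig(seed=0, pa=0.5, beta=0.3)
        bounds = SearchBounds.cube(2, -5.0, 5.0)
        spec = CaputoSpec(alpha=0.7, memory_terms=2, fd_step=0.01)
        f = lambda x: float(np.sum((x - 0.5) ** 2))
        pop = make_ranked_pop([[0.4, 0.4], [0.6, 0.7], [1.5, -1.0]], f)
        derivs = derivative_table(f, pop.best.position, 2, spec.fd_step)

        class HalfMaskRng:
            def uniform(self, low=0.0, high=1.0, size=None):
                return np.array([0.0, 0.9])  # coord 0 on (v<pa), coord 1 off

        from fraccs.caputo import caputo_from_derivatives

        g = caputo_from_derivatives(derivs, pop.best.position, pop.worst.position, spec)
        out = cfo_local_step(
            pop.nests[1], pop, pop.best, derivs, config, spec, bounds, HalfMaskRng()
        )
        expected0 = pop.nests[1].position[0] + 0.3 * g[0]
        assert out[0] == pytest.approx(expected0)
        assert out[1] == pop.nests[1].position[1]


class TestRunCfoCS:
    def test_elitism_and_improvement_at_integer_order(self):
        config = OptimizerConfig(seed=4, alpha=1.0, memory_terms=1, max_iter=50)
        bounds = SearchBounds.cube(5, -5.0, 5.0)
        trace = run_cfo_cs(sphere, bounds, config)
        assert np.all(np.diff(trace.best_fitness_per_iter) <= 0)
        assert trace.best_fitness <= trace.best_fitness_per_iter[0]

    def test_single_iteration_trace_length(self):
        config = OptimizerConfig(seed=5, max_iter=1)
        trace = run_cfo_cs(sphere, SearchBounds.cube(3, -1, 1), config)
        assert len(trace.best_fitness_per_iter) == 1

    def test_positions_respect_bounds_every_evaluation(self):
        bounds = SearchBounds.cube(4, -2.0, 2.0)
        seen = []

        def watched(x):
            seen.append(x.copy())
            return sphere(x)

        run_cfo_cs(watched, bounds, OptimizerConfig(seed=6, max_iter=20))
        arr = np.array(seen)
        # finite-difference stencils probe just outside the incumbent, still
        # inside the box by at most the stencil reach 2h
        reach = 2 * 0.01 * np.mean(bounds.width)
        assert np.all(arr >= bounds.lower - reach)
        assert np.all(arr <= bounds.upper + reach)

    def test_evaluation_budget_with_gradient_overhead(self, fast_config):
        dim = 5
        bounds = SearchBounds.cube(dim, -1.0, 1.0)
        trace = run_cfo_cs(sphere, bounds, fast_config)
        per_iter = fast_config.n_cuckoos_per_iter + n_abandoned(fast_config)
        gradient_cost = 2 * fast_config.memory_terms * dim
        bound = fast_config.max_iter * (per_iter + gradient_cost) + fast_config.n_nests
        assert trace.evaluations <= bound

    def test_full_run_reproducible_from_seed(self, fast_config):
        bounds = SearchBounds.cube(4, -1.0, 1.0)
        t1 = run_cfo_cs(sphere, bounds, fast_config)
        t2 = run_cfo_cs(sphere, bounds, fast_config)
        assert np.array_equal(t1.best_fitness_per_iter, t2.best_fitness_per_iter)
        assert np.array_equal(t1.best_position, t2.best_position)

    def test_outpaces_plain_cs_on_sphere_median_over_seeds(self):
        # paired-seed comparison at equal generation budget
        bounds = SearchBounds.cube(10, -5.0, 5.0)
        cs_finals, cfo_finals = [], []
        for s in range(10):
            cfg = OptimizerConfig(seed=s, max_iter=100, alpha=0.7, memory_terms=4)
            cs_finals.append(run_cs(sphere, bounds, cfg).best_fitness)
            cfo_finals.append(run_cfo_cs(sphere, bounds, cfg).best_fitness)
        assert np.median(cfo_finals) <= np.median(cs_finals)
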