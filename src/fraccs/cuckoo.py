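"""Baseline cuckoo search via Lévy flights.

One generation consists of (i) a batch of cuckoo proposals generated by the
global Lévy walk, each greedily replacing a uniformly chosen nest when
strictly better, and (ii) abandonment of a fraction Pa of the worst nests,
rebuilt by the biased local walk. The best nest is never abandoned, so the
best fitness trace is non-increasing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core import (
    Nest,
    OptimizerConfig,
    Population,
    SearchBounds,
    WORST_FITNESS,
    clip_to_bounds,
    initialize_population,
    rank_population,
)
from .levy import levy_step

logger = logging.getLogger(__name__)

Objective = Callable[[np.ndarray], float]


@dataclass
class OptimizationTrace:
    """Per-iteration best fitness plus the final incumbent."""

    best_fitness_per_iter: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    evaluations: int

    def to_frame(self) -> pd.DataFrame:
        """Two-column table (iteration, best_fitness) for export/plotting."""
        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.best_fitness_per_iter) + 1),
                "best_fitness": self.best_fitness_per_iter,
            }
        )


class _CountedObjective:
    """Wraps the objective: counts calls and maps non-finite values to +inf."""

    def __init__(self, f: Objective):
        self._f = f
        self.calls = 0

    def __call__(self, x: np.ndarray) -> float:
        self.calls += 1
        val = float(self._f(x))
        return val if math.isfinite(val) else WORST_FITNESS


def heaviside(u: np.ndarray) -> np.ndarray:
    """H(u) = 1 for u > 0, else 0 (strict, elementwise)."""
    return (np.asarray(u) > 0).astype(float)


def global_walk_step(
    nest: Nest,
    beta: float,
    levy_lambda: float,
    rng: np.random.Generator,
    bounds: SearchBounds,
) -> np.ndarray:
    """Lévy global walk: x + β ⊗ Lévy(λ), projected back into the box."""
    step = levy_step(nest.position.shape[0], levy_lambda, rng)
    return clip_to_bounds(nest.position + beta * step, bounds)


def local_walk_step(
    nest: Nest,
    pop: Population,
    pa: float,
    beta_s: float,
    rng: np.random.Generator,
    bounds: SearchBounds,
) -> np.ndarray:
    """Biased local walk: x + β_s ⊗ H(Pa − v) ⊗ (x_p − x_q).

    x_p, x_q come from a random permutation of the population; the Heaviside
    mask (one uniform draw v per coordinate) switches each coordinate's move
    on with probability Pa.
    """
    if pop.size < 3:
        raise ValueError("local walk needs a population of at least 3 nests")
    perm = rng.permutation(pop.size)
    p, q = perm[0], perm[1]
    xp, xq = pop.nests[p].position, pop.nests[q].position
    v = rng.uniform(size=nest.position.shape[0])
    mask = heaviside(pa - v)
    return clip_to_bounds(nest.position + beta_s * mask * (xp - xq), bounds)


def n_abandoned(config: OptimizerConfig) -> int:
    return math.ceil(config.pa * config.n_nests)


def run_engine(
    objective: Objective,
    bounds: SearchBounds,
    config: OptimizerConfig,
    global_step: Callable,
    local_step: Callable,
    iteration_setup: Callable | None = None,
) -> OptimizationTrace:
    """Shared generation loop for CS and its fractional-gradient variant.

    ``global_step(nest, pop, f, rng, ctx)`` and
    ``local_step(nest, pop, f, rng, ctx)`` produce candidate positions;
    ``iteration_setup(pop, f, rng)`` runs once per generation and returns a
    context shared by that generation's proposals (the fractional variant
    uses it to precompute the derivative table at the incumbent).
    """
    rng = np.random.default_rng(config.seed)
    f = _CountedObjective(objective)

    pop = initialize_population(bounds, config.n_nests, rng)
    for nest in pop.nests:
        nest.set_fitness(f(nest.position))
    rank_population(pop)

    trace = np.empty(config.max_iter)
    for k in range(config.max_iter):
        pop.iteration = k
        ctx = iteration_setup(pop, f, rng) if iteration_setup else None

        # Cuckoo proposals: global walk, greedy replacement of a random nest.
        for _ in range(config.n_cuckoos_per_iter):
            j = int(rng.integers(pop.size))
            candidate = global_step(pop.nests[j], pop, f, rng, ctx)
            cand_fit = f(candidate)
            l = int(rng.integers(pop.size))
            if cand_fit < pop.nests[l].fitness:
                pop.nests[l] = Nest(position=candidate)
                pop.nests[l].set_fitness(cand_fit)
        rank_population(pop)

        # Abandonment: rebuild the worst ceil(Pa*n) nests, sparing the best.
        order = np.argsort(pop.fitnesses(), kind="stable")[::-1]
        doomed = [int(i) for i in order if int(i) != pop.best_index]
        for i in doomed[: n_abandoned(config)]:
            candidate = local_step(pop.nests[i], pop, f, rng, ctx)
            pop.nests[i] = Nest(position=candidate)
            pop.nests[i].set_fitness(f(candidate))
        rank_population(pop)

        trace[k] = pop.best.fitness

    if not math.isfinite(pop.best.fitness):
        logger.warning("objective returned no finite value; trace is all sentinels")
    return OptimizationTrace(
        best_fitness_per_iter=trace,
        best_position=pop.best.position.copy(),
        best_fitness=float(pop.best.fitness),
        evaluations=f.calls,
    )


def run_cs(
    objective: Objective, bounds: SearchBounds, config: OptimizerConfig
) -> OptimizationTrace:
    """Cuckoo search via Lévy flights over a box, minimizing the objective."""

    def global_step(nest, pop, f, rng, ctx):
        return global_walk_step(nest, config.beta, config.levy_lambda, rng, bounds)

    def local_step(nest, pop, f, rng, ctx):
        return local_walk_step(nest, pop, config.pa, config.beta, rng, bounds)

    return run_engine(objective, bounds, config, global_step, local_step)
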