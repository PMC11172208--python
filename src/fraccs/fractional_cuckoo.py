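"""Cuckoo search driven by a Caputo fractional-order gradient.

The plain Lévy walk explores well but exploits poorly: it never looks at the
local shape of the objective. This variant modulates both walks with the
truncated Caputo fractional gradient of the objective evaluated at the
current best nest:

  exploration:  x_j + β ⊗ Lévy(λ) ⊗ ∇^α_{c_k} f(x_best)
  exploitation: x_j + β ⊗ H(Pa − v) ⊗ ∇^α_{c_k} f(x_best)

The reference point c_k differs between the two phases. During exploration
it is the mean of three randomized points x_j − r_m (x_best − x_j),
r_m ~ U[0,1], which scatters the fractional memory along the line from the
nest toward the incumbent. During exploitation c_k is the worst nest, so the
gradient is taken along the worst-to-best direction — the direction of
maximum improvement across the population.

The sign-balanced Lévy factor randomizes the direction of the exploration
move while the gradient magnitude — which shrinks as the incumbent
approaches a stationary point — acts as an adaptive step size; greedy
accept-if-better replacement discards moves in the wrong direction.

Cost control: the integer-order derivative table f^(v)(x_best), the only
part that consumes objective evaluations, is computed once per generation
and shared by every proposal; assembling the series for each proposal's c_k
is pure arithmetic.
"""

from __future__ import annotations

import numpy as np

from .caputo import CaputoSpec, caputo_from_derivatives, derivative_table
from .core import Nest, OptimizerConfig, Population, SearchBounds, clip_to_bounds
from .cuckoo import (
    Objective,
    OptimizationTrace,
    global_walk_step,
    heaviside,
    local_walk_step,
    run_engine,
)
from .levy import levy_step


def caputo_spec_for(config: OptimizerConfig, bounds: SearchBounds) -> CaputoSpec:
    """Build the Caputo spec with the absolute step h = fd_step × box width."""
    h = float(config.fd_step * np.mean(bounds.width))
    return CaputoSpec(alpha=config.alpha, memory_terms=config.memory_terms, fd_step=h)


def exploration_reference(
    nest: Nest, best: Nest, rng: np.random.Generator
) -> np.ndarray:
    """Mean of x_j − r_m (x_best − x_j) over three uniform draws r_1..r_3."""
    r = rng.uniform(size=3)
    pts = [nest.position - rm * (best.position - nest.position) for rm in r]
    return np.mean(pts, axis=0)


def _sanitize(g: np.ndarray) -> np.ndarray:
    # sentinel stencil values contribute no direction rather than poisoning
    # the whole move
    return np.nan_to_num(g, nan=0.0, posinf=0.0, neginf=0.0)


def cfo_global_step(
    nest: Nest,
    best: Nest,
    derivs: np.ndarray,
    config: OptimizerConfig,
    spec: CaputoSpec,
    bounds: SearchBounds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exploration move: x_j + β ⊗ Lévy(λ) ⊗ ∇^α f(x_best), clipped."""
    ck = exploration_reference(nest, best, rng)
    g = _sanitize(caputo_from_derivatives(derivs, best.position, ck, spec))
    step = levy_step(nest.position.shape[0], config.levy_lambda, rng)
    return clip_to_bounds(nest.position + config.beta * step * g, bounds)


def cfo_local_step(
    nest: Nest,
    pop: Population,
    best: Nest,
    derivs: np.ndarray,
    config: OptimizerConfig,
    spec: CaputoSpec,
    bounds: SearchBounds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exploitation move: x_j + β ⊗ H(Pa − v) ⊗ ∇^α f(x_best), c_k = x_worst."""
    g = _sanitize(
        caputo_from_derivatives(derivs, best.position, pop.worst.position, spec)
    )
    v = rng.uniform(size=nest.position.shape[0])
    mask = heaviside(config.pa - v)
    return clip_to_bounds(nest.position + config.beta * mask * g, bounds)


def run_cfo_cs(
    objective: Objective, bounds: SearchBounds, config: OptimizerConfig
) -> OptimizationTrace:
    """Fractional-gradient cuckoo search; same control flow as :func:`run_cs`.

    Degenerate-modulation fallback: when the fractional gradient vanishes
    identically for a proposal (reference point coincident with the
    incumbent — e.g. the donor nest *is* the incumbent — or a locally flat
    objective), the update rule would emit an exact copy of the donor. Such
    copies carry no information, and because greedy replacement happily
    propagates them they collapse the population onto the incumbent and
    freeze the search. In that case the proposal falls back to the
    corresponding unmodulated walk of plain cuckoo search, preserving
    ergodicity; every informative proposal uses the fractional rule.
    """
    spec = caputo_spec_for(config, bounds)

    def iteration_setup(pop, f, rng):
        # snapshot the incumbent: the derivative table is valid at exactly
        # this position even if greedy replacement improves the best nest
        # mid-generation
        best = Nest(position=pop.best.position.copy())
        best.set_fitness(pop.best.fitness)
        derivs = derivative_table(f, best.position, spec.memory_terms, spec.fd_step)
        return best, derivs

    def global_step(nest, pop, f, rng, ctx):
        best, derivs = ctx
        ck = exploration_reference(nest, best, rng)
        g = _sanitize(caputo_from_derivatives(derivs, best.position, ck, spec))
        if not g.any():
            return global_walk_step(nest, config.beta, config.levy_lambda, rng, bounds)
        step = levy_step(nest.position.shape[0], config.levy_lambda, rng)
        return clip_to_bounds(nest.position + config.beta * step * g, bounds)

    def local_step(nest, pop, f, rng, ctx):
        best, derivs = ctx
        g = _sanitize(
            caputo_from_derivatives(derivs, best.position, pop.worst.position, spec)
        )
        if not g.any():
            return local_walk_step(nest, pop, config.pa, config.beta, rng, bounds)
        v = rng.uniform(size=nest.position.shape[0])
        mask = heaviside(config.pa - v)
        return clip_to_bounds(nest.position + config.beta * mask * g, bounds)

    return run_engine(
        objective, bounds, config, global_step, local_step, iteration_setup
    )
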