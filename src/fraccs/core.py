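"""Population data structures shared by the cuckoo-search optimizers.

Nests hold real-valued positions inside a box; fitness is minimized.
Unevaluated or infeasible nests carry ``WORST_FITNESS`` (+inf) so that
greedy replacement always rejects them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

WORST_FITNESS = np.inf


@dataclass(frozen=True)
class SearchBounds:
    """Axis-aligned box constraint: ``lower[j] <= x[j] <= upper[j]``."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.ndim != 1 or lower.shape != upper.shape:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if not np.all(lower < upper):
            raise ValueError("each lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dim(self) -> int:
        return self.lower.shape[0]

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    @classmethod
    def unit(cls, dim: int) -> "SearchBounds":
        """The unit box [0, 1]^dim used for binary-encoded feature selection."""
        return cls(np.zeros(dim), np.ones(dim))

    @classmethod
    def cube(cls, dim: int, lo: float, hi: float) -> "SearchBounds":
        return cls(np.full(dim, float(lo)), np.full(dim, float(hi)))


@dataclass
class Nest:
    """One candidate solution: a position and its (cached) objective value.

    ``fitness`` stays at the worst sentinel until :meth:`set_fitness` is
    called; infeasible evaluations may also assign the sentinel, so the
    ``evaluated`` flag distinguishes "never scored" from "scored infeasible".
    """

    position: np.ndarray
    fitness: float = WORST_FITNESS
    evaluated: bool = False

    def set_fitness(self, value: float) -> None:
        self.fitness = WORST_FITNESS if not np.isfinite(value) else float(value)
        self.evaluated = True


@dataclass
class Population:
    """Ordered collection of nests with best/worst bookkeeping.

    ``best_index``/``worst_index`` are maintained by :func:`rank_population`;
    ties break toward the lowest nest index for seeded reproducibility.
    """

    nests: list[Nest]
    best_index: int = 0
    worst_index: int = 0
    iteration: int = 0

    def __post_init__(self) -> None:
        if len(self.nests) < 2:
            raise ValueError("population needs at least 2 nests")

    @property
    def size(self) -> int:
        return len(self.nests)

    @property
    def best(self) -> Nest:
        return self.nests[self.best_index]

    @property
    def worst(self) -> Nest:
        return self.nests[self.worst_index]

    def fitnesses(self) -> np.ndarray:
        return np.array([n.fitness for n in self.nests])


@dataclass(frozen=True)
class OptimizerConfig:
    """All optimizer parameters.

    Defaults follow the study configuration: 15 persistent nests, 10 cuckoo
    proposals per generation, abandonment probability ``pa = 0.25``, step
    scale ``beta = 0.3``, Lévy exponent 1.5, 100 generations; the fractional
    machinery uses order ``alpha = 0.7`` with ``memory_terms = 4`` series
    terms and a relative finite-difference step of 1e-2 of the box width.
    """

    n_nests: int = 15
    n_cuckoos_per_iter: int = 10
    pa: float = 0.25
    beta: float = 0.3
    levy_lambda: float = 1.5
    max_iter: int = 100
    alpha: float = 0.7
    memory_terms: int = 4
    fd_step: float = 1e-2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pa <= 1.0:
            raise ValueError("pa must lie in [0, 1]")
        if not 1.0 < self.levy_lambda < 2.0:
            raise ValueError("levy_lambda must lie in (1, 2)")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.memory_terms < 1:
            raise ValueError("memory_terms must be >= 1")
        if self.n_nests < 2:
            raise ValueError("n_nests must be >= 2")
        if self.fd_step <= 0:
            raise ValueError("fd_step must be positive")

    def with_seed(self, seed: int) -> "OptimizerConfig":
        return replace(self, seed=seed)


def initialize_population(
    bounds: SearchBounds, n: int, rng: np.random.Generator
) -> Population:
    """Draw ``n`` nests uniformly inside the box: ``x_j = lb + r (ub - lb)``.

    Fitness is left at the worst sentinel; evaluation happens in the
    optimizer loop.
    """
    if n < 2:
        raise ValueError("population size must be >= 2")
    r = rng.uniform(size=(n, bounds.dim))
    positions = bounds.lower + r * bounds.width
    return Population(nests=[Nest(position=p) for p in positions])


def clip_to_bounds(position: np.ndarray, bounds: SearchBounds) -> np.ndarray:
    """Project a position onto the box, coordinate by coordinate."""
    position = np.asarray(position, dtype=float)
    if position.shape != bounds.lower.shape:
        raise ValueError(
            f"position has length {position.shape}, bounds expect {bounds.lower.shape}"
        )
    return np.clip(position, bounds.lower, bounds.upper)


def rank_population(pop: Population) -> Population:
    """Refresh best/worst indices (argmin/argmax of fitness, stable ties).

    Raises if any nest is still unevaluated: ranking a half-evaluated
    population would silently treat sentinels as real values.
    """
    for i, nest in enumerate(pop.nests):
        if not nest.evaluated:
            raise RuntimeError(f"nest {i} has no fitness; evaluate before ranking")
    fits = pop.fitnesses()
    pop.best_index = int(np.argmin(fits))
    pop.worst_index = int(np.argmax(fits))
    return pop
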