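"""Standard continuous test functions for optimizer benchmarking."""

from __future__ import annotations

import numpy as np

from .core import SearchBounds


def sphere(x: np.ndarray) -> float:
    return float(np.sum(np.square(x)))


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x)
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


def rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


#: name -> (function, default box half-width); minimum at the origin except
#: rosenbrock (at the all-ones point)
BENCHMARKS = {
    "sphere": (sphere, 5.0),
    "rastrigin": (rastrigin, 5.12),
    "rosenbrock": (rosenbrock, 2.048),
}


def benchmark_bounds(name: str, dim: int) -> SearchBounds:
    if name not in BENCHMARKS:
        raise ValueError(f"unknown benchmark {name!r}; choose from {sorted(BENCHMARKS)}")
    _, half = BENCHMARKS[name]
    return SearchBounds.cube(dim, -half, half)
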