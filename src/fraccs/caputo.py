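"""Truncated Caputo fractional-order gradient of a black-box objective.

The Caputo derivative of order α ∈ (0, 1] of f on [c, x] admits a series
expansion in ordinary higher derivatives,

    D^α_c f(x) = Σ_{v≥1} f^(v)(x) / Γ(v+1−α) · (x − c)^(v−α),

which is truncated after M "memory" terms (M ≤ 4 keeps the cost of the
finite-difference stencils acceptable). The gradient is assembled
coordinate-wise: each component treats f as a one-variable function of that
coordinate, with all others frozen, and uses its own reference coordinate
c_i. For α = 1, M = 1 the series collapses to the ordinary gradient.

The objective is a black box, so the integer-order derivatives f^(v) are
estimated with central finite differences of step h. Because the series is
linear in those derivatives, the expensive part (the stencil evaluations at
x) can be computed once and re-used for any number of reference points; see
:func:`derivative_table` / :func:`caputo_from_derivatives`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma

MAX_ORDER = 4


@dataclass(frozen=True)
class CaputoSpec:
    """Fractional order α, series length M, and finite-difference step h."""

    alpha: float = 0.7
    memory_terms: int = 4
    fd_step: float = 1e-2

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if not 1 <= self.memory_terms <= MAX_ORDER:
            raise ValueError(f"memory_terms must lie in 1..{MAX_ORDER}")
        if self.fd_step <= 0:
            raise ValueError("fd_step must be positive")


def estimate_derivative(f, x: np.ndarray, coord: int, order: int, h: float) -> float:
    """Central finite-difference estimate of the order-th partial along coord.

    Stencils (exact on polynomials up to the stencil's degree + 1):
      v=1: (f(x+h) − f(x−h)) / 2h
      v=2: (f(x+h) − 2f(x) + f(x−h)) / h²
      v=3: (f(x+2h) − 2f(x+h) + 2f(x−h) − f(x−2h)) / 2h³
      v=4: (f(x+2h) − 4f(x+h) + 6f(x) − 4f(x−h) + f(x−2h)) / h⁴

    A non-finite objective value anywhere on the stencil propagates as NaN.
    """
    if not 1 <= order <= MAX_ORDER:
        raise ValueError(f"derivative order must lie in 1..{MAX_ORDER}, got {order}")
    if h <= 0:
        raise ValueError("step h must be positive")
    x = np.asarray(x, dtype=float)

    def at(offset: float) -> float:
        p = x.copy()
        p[coord] += offset
        return float(f(p))

    if order == 1:
        vals = (at(h), at(-h))
        est = (vals[0] - vals[1]) / (2.0 * h)
    elif order == 2:
        vals = (at(h), at(0.0), at(-h))
        est = (vals[0] - 2.0 * vals[1] + vals[2]) / h**2
    elif order == 3:
        vals = (at(2 * h), at(h), at(-h), at(-2 * h))
        est = (vals[0] - 2.0 * vals[1] + 2.0 * vals[2] - vals[3]) / (2.0 * h**3)
    else:
        vals = (at(2 * h), at(h), at(0.0), at(-h), at(-2 * h))
        est = (vals[0] - 4.0 * vals[1] + 6.0 * vals[2] - 4.0 * vals[3] + vals[4]) / h**4
    if not all(np.isfinite(v) for v in vals):
        return float("nan")
    return float(est)


def derivative_table(f, x: np.ndarray, max_order: int, h: float) -> np.ndarray:
    """All partial derivatives f^(v), v = 1..max_order, at x.

    Returns an array of shape (max_order, dim). Stencil points are shared
    across orders per coordinate: f(x) once, plus x ± h (always) and x ± 2h
    (orders ≥ 3) per coordinate, so the objective-call count is at most
    1 + 4·dim regardless of max_order.
    """
    if not 1 <= max_order <= MAX_ORDER:
        raise ValueError(f"max_order must lie in 1..{MAX_ORDER}")
    x = np.asarray(x, dtype=float)
    dim = x.shape[0]
    need_center = max_order >= 2
    need_wide = max_order >= 3
    f0 = float(f(x)) if need_center else 0.0
    table = np.zeros((max_order, dim))
    for i in range(dim):
        p = x.copy()

        def at(offset: float) -> float:
            p[i] = x[i] + offset
            val = float(f(p))
            p[i] = x[i]
            return val

        fp, fm = at(h), at(-h)
        table[0, i] = (fp - fm) / (2.0 * h)
        if max_order >= 2:
            table[1, i] = (fp - 2.0 * f0 + fm) / h**2
        if need_wide:
            fpp, fmm = at(2.0 * h), at(-2.0 * h)
            table[2, i] = (fpp - 2.0 * fp + 2.0 * fm - fmm) / (2.0 * h**3)
            if max_order >= 4:
                table[3, i] = (
                    fpp - 4.0 * fp + 6.0 * f0 - 4.0 * fm + fmm
                ) / h**4
    table[~np.isfinite(table)] = np.nan
    return table


def fractional_power(d: np.ndarray, exponent: float) -> np.ndarray:
    """(x − c)^(v−α) with a real-valued branch for negative bases.

    For non-integer exponents the principal power of a negative number is
    complex, so the sign is factored out: sign(d)·|d|^e, with d = 0 mapping
    to 0. Integer exponents (which arise only at α = 1) use the plain real
    power so that the one-term series reduces exactly to the ordinary
    gradient (d^0 = 1), matching the Caputo derivative of integer order
    being independent of the reference point.
    """
    d = np.asarray(d, dtype=float)
    if float(exponent).is_integer():
        return d ** int(exponent)
    return np.sign(d) * np.abs(d) ** exponent


def caputo_from_derivatives(
    derivs: np.ndarray, x: np.ndarray, ck: np.ndarray, spec: CaputoSpec
) -> np.ndarray:
    """Assemble the truncated Caputo gradient from precomputed f^(v)(x).

    Per coordinate i:  Σ_{v=1}^{M} derivs[v−1, i] · (x_i − ck_i)^(v−α) / Γ(v+1−α).
    """
    x = np.asarray(x, dtype=float)
    ck = np.asarray(ck, dtype=float)
    if x.shape != ck.shape:
        raise ValueError("x and ck must have the same length")
    m = spec.memory_terms
    if derivs.shape[0] < m:
        raise ValueError("derivative table shorter than memory_terms")
    d = x - ck
    grad = np.zeros_like(x)
    for v in range(1, m + 1):
        grad += (
            derivs[v - 1] * fractional_power(d, v - spec.alpha) / gamma(v + 1.0 - spec.alpha)
        )
    return grad


def caputo_gradient(f, x: np.ndarray, ck: np.ndarray, spec: CaputoSpec) -> np.ndarray:
    """Coordinate-wise truncated Caputo fractional gradient of f at x.

    Derivatives are estimated by finite differences with step ``spec.fd_step``
    (an absolute step; callers scale it to the box width).
    """
    x = np.asarray(x, dtype=float)
    derivs = derivative_table(f, x, spec.memory_terms, spec.fd_step)
    return caputo_from_derivatives(derivs, x, ck, spec)
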