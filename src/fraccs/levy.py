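"""Heavy-tailed Lévy step sampling via Mantegna's algorithm.

The global random walk of cuckoo search perturbs positions with steps whose
magnitude follows the power-law tail u ~ k^(-λ), 1 < λ < 3: many small moves
punctuated by rare long jumps. Mantegna's construction realizes this with the
ratio of two Gaussians, ``step = u / |v|^(1/λ)`` where ``u ~ N(0, σ_u²)``
and ``v ~ N(0, 1)``, with σ_u chosen so the ratio is (approximately)
λ-stable.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gamma


def levy_sigma(levy_lambda: float) -> float:
    """Mantegna scale constant σ_u for tail exponent ``levy_lambda``.

    σ_u = [Γ(1+λ) sin(πλ/2) / (Γ((1+λ)/2) λ 2^((λ−1)/2))]^(1/λ).
    For λ = 1.5 this is ≈ 0.6966.

    The constant is real and positive only for λ in the open interval
    (1, 2): sin(πλ/2) vanishes at λ = 2 and turns negative beyond it,
    so exponents outside (1, 2) are rejected.
    """
    lam = float(levy_lambda)
    if not 1.0 < lam < 2.0:
        raise ValueError(f"levy exponent must lie in (1, 2), got {lam}")
    num = gamma(1.0 + lam) * np.sin(np.pi * lam / 2.0)
    den = gamma((1.0 + lam) / 2.0) * lam * 2.0 ** ((lam - 1.0) / 2.0)
    return float((num / den) ** (1.0 / lam))


def levy_step(dim: int, levy_lambda: float, rng: np.random.Generator) -> np.ndarray:
    """Sample one Lévy step vector of length ``dim``.

    Each coordinate is an independent Mantegna draw; signs are balanced
    (u is symmetric), so per-coordinate medians sit near zero while the
    magnitude distribution is heavy-tailed with exponent ``levy_lambda``.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    sigma = levy_sigma(levy_lambda)
    u = rng.normal(0.0, sigma, size=dim)
    v = rng.normal(0.0, 1.0, size=dim)
    return u / np.abs(v) ** (1.0 / levy_lambda)
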