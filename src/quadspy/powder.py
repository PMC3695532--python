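"""ZCW orientation sets and weighted powder averaging.

Three-angle orientation sets are built as a rank-1 quasi-uniform lattice
on (cosβ, γ, α) — the ZCW construction generalised to three angles: the
j-th point is ``u_j = frac((j + 1/2)·(1, g₁, g₂)/N)`` mapped to
``cosβ = 1 − 2u₁``, ``γ = 2π u₂``, ``α = 2π u₃``, with golden-ratio
generators ``g₁ ≈ N/φ``, ``g₂ ≈ N/φ²`` chosen coprime with N.  Weights
are uniform.  The unit generator sits on cosβ so that the two projections
that control convergence — (β, γ) for the static tensor geometry and
(β, α) for the rotor-phase interference — are both Fibonacci-quality.

The shipped set sizes follow the Fibonacci-derived ZCW sequence, plus
the two reference sizes 1154 and 6044 used for the published simulation
conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PowderScheme", "zcw_sizes", "zcw_set", "powder_average", "single_crystal"]

_GOLDEN = (1 + np.sqrt(5)) / 2

_FIBONACCI_SIZES = (21, 34, 55, 89, 144, 233, 377, 610, 987, 1597, 2584, 4181, 6765)
_REFERENCE_SIZES = (1154, 6044)


@dataclass(frozen=True)
class PowderScheme:
    """Crystallite Euler angles (degrees) with normalised weights."""

    orientations_deg: np.ndarray  # (N, 3)
    weights: np.ndarray  # (N,)

    def __post_init__(self):
        if self.orientations_deg.shape != (len(self.weights), 3):
            raise ValueError("orientations and weights are inconsistent")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if not math.isclose(float(self.weights.sum()), 1.0, rel_tol=1e-12):
            raise ValueError("weights must sum to 1")

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def orientations_rad(self) -> np.ndarray:
        return np.radians(self.orientations_deg)


def zcw_sizes() -> tuple[int, ...]:
    """Valid ZCW set sizes, ascending."""
    return tuple(sorted(_FIBONACCI_SIZES + _REFERENCE_SIZES))


def _coprime_near(target: float, n: int, avoid: set[int]) -> int:
    g0 = max(2, int(round(target)))
    for delta in range(0, n):
        for g in (g0 + delta, g0 - delta):
            if 1 < g < n and math.gcd(g, n) == 1 and g not in avoid:
                return g
    raise RuntimeError("no coprime generator found")  # pragma: no cover


def zcw_set(count: int) -> PowderScheme:
    """Deterministic three-angle ZCW orientation set of exactly ``count``
    crystallites with uniform weights.

    Raises
    ------
    ValueError
        for counts outside the shipped size sequence; the message names
        the nearest valid sizes.
    """
    sizes = zcw_sizes()
    if count not in sizes:
        below = max((s for s in sizes if s < count), default=None)
        above = min((s for s in sizes if s > count), default=None)
        near = ", ".join(str(s) for s in (below, above) if s is not None)
        raise ValueError(f"{count} is not a valid ZCW set size; nearest valid sizes: {near}")
    g1 = _coprime_near(count / _GOLDEN, count, avoid=set())
    g2 = _coprime_near(count / _GOLDEN**2, count, avoid={g1})
    j = np.arange(count) + 0.5
    cos_beta = 1 - 2 * ((j / count) % 1.0)
    gamma = 2 * np.pi * ((j * g1 / count) % 1.0)
    alpha = 2 * np.pi * ((j * g2 / count) % 1.0)
    ang = np.degrees(np.column_stack([alpha, np.arccos(cos_beta), gamma]))
    return PowderScheme(ang, np.full(count, 1.0 / count))


def single_crystal(alpha_deg: float, beta_deg: float, gamma_deg: float) -> PowderScheme:
    """A one-orientation 'powder' (useful for tests and diagnostics)."""
    return PowderScheme(np.array([[alpha_deg, beta_deg, gamma_deg]]), np.array([1.0]))


def powder_average(per_orientation_values, scheme: PowderScheme):
    """Weighted average over the scheme; values may be scalars or arrays
    (one leading entry per orientation)."""
    values = np.asarray(per_orientation_values)
    if values.shape[0] != len(scheme):
        raise ValueError(
            f"got {values.shape[0]} values for {len(scheme)} orientations"
        )
    return np.tensordot(scheme.weights, values, axes=(0, 0))
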