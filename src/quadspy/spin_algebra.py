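"""Angular-momentum algebra for the coupled ¹³C–¹⁴N spin pair.

The simulator works on the 6-dimensional product space of a spin-1/2
(¹³C, the "spy" nucleus) and a spin-1 (¹⁴N).  This module provides the
single-spin operator sets, irreducible spherical tensor operators,
embedding into the coupled space, and the decomposition of a density
operator into ¹⁴N coherence orders.

Conventions
-----------
* Zeeman product basis ``|m_S⟩ ⊗ |m_I⟩`` with magnetic quantum numbers
  ordered ``m = +I … −I`` on both spins; ¹³C is the first factor.
* Coherence order ``p`` of a matrix element ``|m_r⟩⟨m_c|`` on ¹⁴N is
  ``p = m_r − m_c`` so that ``I⁺``-like terms carry ``p = +1`` and the
  component of order ``p`` picks up ``e^{−ipφ}`` under a ¹⁴N z-rotation
  by ``φ``.
* ``spherical_tensor`` returns operators normalised to unit Frobenius
  norm, making coherence-amplitude ratios basis-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

import numpy as np

__all__ = [
    "SpinLabel",
    "DIM",
    "spin_matrices",
    "spherical_tensor",
    "embed",
    "coherence_order_matrix",
    "coherence_mask",
    "coherence_decompose",
    "coherence_orders",
    "product_basis",
]


class SpinLabel(Enum):
    """The two nuclei of the simulated pair."""

    C13 = 0.5
    N14 = 1.0

    @property
    def quantum_number(self) -> float:
        return self.value

    @property
    def dim(self) -> int:
        return int(round(2 * self.value + 1))


#: dimension of the coupled space (2 × 3)
DIM = SpinLabel.C13.dim * SpinLabel.N14.dim


def _check_spin(s: float) -> float:
    if s not in (0.5, 1.0):
        raise ValueError(f"unsupported spin quantum number {s!r}; expected 1/2 or 1")
    return float(s)


@lru_cache(maxsize=None)
def _spin_matrices_cached(s: float):
    dim = int(round(2 * s + 1))
    m = np.arange(s, -s - 1.0, -1.0)
    Iz = np.diag(m).astype(complex)
    Ip = np.zeros((dim, dim), complex)
    for i in range(1, dim):
        Ip[i - 1, i] = np.sqrt(s * (s + 1) - m[i] * (m[i] + 1))
    Im = Ip.conj().T
    mats = {
        "x": (Ip + Im) / 2,
        "y": (Ip - Im) / 2j,
        "z": Iz,
        "+": Ip,
        "-": Im,
        "id": np.eye(dim, dtype=complex),
    }
    for v in mats.values():
        v.setflags(write=False)
    return mats


def spin_matrices(quantum_number: float) -> dict:
    """Cartesian and ladder operators ``{x, y, z, +, -, id}`` in the
    Zeeman basis ordered ``m = +I … −I``."""
    return dict(_spin_matrices_cached(_check_spin(quantum_number)))


def _racah_tensor(s: float, l: int, m: int) -> np.ndarray:
    """Unnormalised (Racah) irreducible spherical tensor operator."""
    ops = _spin_matrices_cached(s)
    Iz, Ip, Im = ops["z"], ops["+"], ops["-"]
    eye = ops["id"]
    isq = Iz @ Iz + ops["x"] @ ops["x"] + ops["y"] @ ops["y"]
    if l == 0:
        return eye.copy()
    if l == 1:
        return {1: -Ip / np.sqrt(2), 0: Iz.copy(), -1: Im / np.sqrt(2)}[m]
    if l == 2:
        return {
            2: Ip @ Ip / 2,
            1: -(Iz @ Ip + Ip @ Iz) / 2,
            0: (3 * Iz @ Iz - isq) / np.sqrt(6),
            -1: (Iz @ Im + Im @ Iz) / 2,
            -2: Im @ Im / 2,
        }[m]
    raise ValueError(f"rank {l} not available")


def spherical_tensor(quantum_number: float, l: int, m: int) -> np.ndarray:
    """Irreducible spherical tensor operator ``T_{l,m}``, unit Frobenius norm.

    Satisfies ``T_{l,m}† = (−1)^m T_{l,−m}`` and
    ``Tr(T_{l,m}† T_{l',m'}) = δ_{ll'} δ_{mm'}``.

    Raises
    ------
    ValueError
        if ``l > 2I`` or ``|m| > l``.
    """
    s = _check_spin(quantum_number)
    if not (0 <= l <= int(round(2 * s))):
        raise ValueError(f"rank l={l} invalid for spin {s} (need 0 ≤ l ≤ {int(round(2*s))})")
    if abs(m) > l:
        raise ValueError(f"component m={m} invalid for rank l={l}")
    T = _racah_tensor(s, l, m)
    return T / np.linalg.norm(T)


def embed(op: np.ndarray, spin: SpinLabel) -> np.ndarray:
    """Extend a single-spin operator to the 6-dimensional coupled space.

    ``embed(A, C13) = A ⊗ 1₃`` and ``embed(B, N14) = 1₂ ⊗ B``; embedded
    operators of different spins commute by construction.
    """
    op = np.asarray(op, dtype=complex)
    if op.shape != (spin.dim, spin.dim):
        raise ValueError(
            f"operator of shape {op.shape} does not match spin {spin.name} "
            f"(expected {(spin.dim, spin.dim)})"
        )
    if spin is SpinLabel.C13:
        return np.kron(op, np.eye(SpinLabel.N14.dim, dtype=complex))
    return np.kron(np.eye(SpinLabel.C13.dim, dtype=complex), op)


def product_basis() -> list[tuple[float, float]]:
    """List of ``(m_S, m_I)`` pairs labelling the 6 basis states, in order."""
    mS = [0.5, -0.5]
    mI = [1.0, 0.0, -1.0]
    return [(a, b) for a in mS for b in mI]


@lru_cache(maxsize=None)
def coherence_order_matrix() -> np.ndarray:
    """6×6 integer matrix of ¹⁴N coherence orders ``p = m_I(row) − m_I(col)``."""
    mI = np.array([mi for _, mi in product_basis()])
    p = (mI[:, None] - mI[None, :]).astype(int)
    p.setflags(write=False)
    return p


@lru_cache(maxsize=None)
def coherence_mask(*orders: int) -> np.ndarray:
    """Boolean mask selecting the matrix elements of the given ¹⁴N orders."""
    p = coherence_order_matrix()
    mask = np.zeros_like(p, dtype=bool)
    for q in orders:
        mask |= p == q
    mask.setflags(write=False)
    return mask


def coherence_decompose(rho: np.ndarray) -> dict[int, np.ndarray]:
    """Split ``rho`` into its ¹⁴N coherence-order components.

    Returns a mapping ``p → component`` for ``p ∈ {−2 … +2}``; the
    components sum to ``rho`` exactly and component ``p`` transforms as
    ``e^{−ipφ}`` under ``e^{−iφ Iz} rho e^{+iφ Iz}``.
    """
    rho = np.asarray(rho, dtype=complex)
    if rho.shape[-2:] != (DIM, DIM):
        raise ValueError(f"expected trailing shape {(DIM, DIM)}, got {rho.shape}")
    return {p: rho * coherence_mask(p) for p in range(-2, 3)}


def coherence_orders(op: np.ndarray, tol: float = 1e-12) -> set[int]:
    """Set of ¹⁴N coherence orders present in ``op`` above ``tol``."""
    comps = coherence_decompose(op)
    return {p for p, c in comps.items() if np.max(np.abs(c)) > tol}


@dataclass(frozen=True)
class PairOperators:
    """Frequently used embedded operators of the ¹³C–¹⁴N pair."""

    Sx: np.ndarray
    Sy: np.ndarray
    Sz: np.ndarray
    Sp: np.ndarray
    Sm: np.ndarray
    Ix: np.ndarray
    Iy: np.ndarray
    Iz: np.ndarray
    Ip: np.ndarray
    Im: np.ndarray


@lru_cache(maxsize=1)
def pair_operators() -> PairOperators:
    C = _spin_matrices_cached(0.5)
    N = _spin_matrices_cached(1.0)
    return PairOperators(
        Sx=embed(C["x"], SpinLabel.C13),
        Sy=embed(C["y"], SpinLabel.C13),
        Sz=embed(C["z"], SpinLabel.C13),
        Sp=embed(C["+"], SpinLabel.C13),
        Sm=embed(C["-"], SpinLabel.C13),
        Ix=embed(N["x"], SpinLabel.N14),
        Iy=embed(N["y"], SpinLabel.N14),
        Iz=embed(N["z"], SpinLabel.N14),
        Ip=embed(N["+"], SpinLabel.N14),
        Im=embed(N["-"], SpinLabel.N14),
    )
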