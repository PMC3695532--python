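"""Spin interactions and the time-dependent rotating-frame Hamiltonian.

The model is a single ¹³C–¹⁴N pair under magic-angle spinning:

* first-order (secular) ¹⁴N quadrupole coupling, MHz scale;
* second-order corrections obtained by instantaneous static perturbation
  theory at each time point — both the quadrupole self-terms (scaling as
  ω_Q²/ω₀) and the quadrupole–dipole cross terms (the residual dipolar
  splittings that survive MAS and mediate transfer to the spy nucleus);
* secular heteronuclear dipole coupling with its MAS time dependence;
* scalar (J) coupling, secular part;
* rf irradiation and resonance offsets on either channel.

Frame chain and conventions
---------------------------
All rotations are active ZYZ.  Rank-2 spatial tensors are transported as

    quadrupole PAS --(α,β,γ of the preset)--> dipolar PAS
                   --(crystallite angles)---> rotor frame
                   --(0, θ_rotor, ω_r t)----> laboratory frame

with ``A'_{m'} = Σ_m D²_{m'm}(Ω) A_m`` and
``D²_{m'm}(α,β,γ) = e^{−im'α} d²_{m'm}(β) e^{−imγ}``.  Component arrays
are indexed ``m = −2 … +2``.

With this convention the static first-order spin-1 eigenfrequencies are
``±(3C_Q/8)(3cos²β − 1 − η sin²β cos2γ)`` for a crystallite at Euler
angles (α, β, γ).

Zeeman energies are taken as ``−(ω_{0S} m_S + ω_{0I} m_I)`` (positive
gyromagnetic ratios), so the second-order shift of the spin-1 SQ
transitions appears at positive (deshielded) frequency, isotropic part
``+(3/40)(C_Q²/ν₀)(1 + η²/3)``.  A resonance offset Δ (site minus
carrier, positive = higher ppm) enters the rotating frame as ``−2πΔ·Iz``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .spin_algebra import SpinLabel, _racah_tensor, embed, pair_operators

__all__ = [
    "MAGIC_ANGLE_DEG",
    "QuadrupoleInteraction",
    "DipolarInteraction",
    "FieldSpec",
    "RfPulseSpec",
    "SpinSystemSpec",
    "wigner_d2",
    "wigner_D2",
    "wigner_rotate",
    "quad_pas_components",
    "dipole_pas_components",
    "mas_fourier_coefficients",
    "HamiltonianGenerator",
    "hamiltonian_at",
]

#: exact magic angle, arccos(1/√3), in degrees
MAGIC_ANGLE_DEG = float(np.degrees(np.arccos(1.0 / np.sqrt(3.0))))

_M2 = np.arange(-2, 3)


@dataclass(frozen=True)
class QuadrupoleInteraction:
    """¹⁴N quadrupole coupling.

    Parameters
    ----------
    cq_mhz : C_Q = e²qQ/h in MHz (sign as printed).
    eta : asymmetry parameter of the EFG tensor, 0 ≤ η ≤ 1.
    euler_to_dipole_deg : active ZYZ Euler angles (degrees) carrying the
        quadrupole PAS into the dipolar frame.
    """

    cq_mhz: float
    eta: float
    euler_to_dipole_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: which way the Euler angles carry the frames: the documented default
    #: rotates the quadrupole PAS into the dipolar frame; "dipole_to_quad"
    #: applies the inverse reading (only a lineshape comparison against a
    #: known sample discriminates the two for non-collinear tensors).
    euler_sense: str = "quad_to_dipole"

    def __post_init__(self):
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must lie in [0, 1], got {self.eta}")
        if self.euler_sense not in ("quad_to_dipole", "dipole_to_quad"):
            raise ValueError(f"unknown euler_sense {self.euler_sense!r}")


@dataclass(frozen=True)
class DipolarInteraction:
    """Heteronuclear dipole coupling b_IS/2π in kHz (signed, axially
    symmetric) plus an optional scalar coupling J in Hz."""

    coupling_khz: float
    j_hz: float = 0.0


@dataclass(frozen=True)
class FieldSpec:
    """Static field, spinning and rotor geometry."""

    larmor_13c_mhz: float = 150.0
    larmor_14n_mhz: float = 43.5
    mas_rate_khz: float = 25.0
    rotor_axis_angle_deg: float = MAGIC_ANGLE_DEG

    def __post_init__(self):
        if self.mas_rate_khz <= 0:
            raise ValueError("mas_rate_khz must be positive")

    @property
    def rotor_period_s(self) -> float:
        return 1e-3 / self.mas_rate_khz


@dataclass(frozen=True)
class RfPulseSpec:
    """Continuous-wave rf irradiation on one channel."""

    channel: SpinLabel
    nutation_khz: float
    phase_deg: float = 0.0
    offset_khz: float = 0.0

    def __post_init__(self):
        if self.nutation_khz < 0:
            raise ValueError("nutation_khz must be ≥ 0")


@dataclass(frozen=True)
class SpinSystemSpec:
    """Complete parameter set for one ¹³C–¹⁴N pair."""

    quadrupole: QuadrupoleInteraction
    dipole: DipolarInteraction
    fields: FieldSpec = field(default_factory=FieldSpec)
    offset_n_khz: float = 0.0
    offset_c_khz: float = 0.0

    def with_offsets(self, offset_n_khz=None, offset_c_khz=None) -> "SpinSystemSpec":
        kw = {}
        if offset_n_khz is not None:
            kw["offset_n_khz"] = offset_n_khz
        if offset_c_khz is not None:
            kw["offset_c_khz"] = offset_c_khz
        return replace(self, **kw)


# ----------------------------------------------------------------------
# Wigner rotations
# ----------------------------------------------------------------------

def _jy_rank2() -> tuple[np.ndarray, np.ndarray]:
    jp = np.zeros((5, 5), complex)
    for i, m in enumerate(_M2[:-1]):
        jp[i + 1, i] = np.sqrt(6 - m * (m + 1))
    jy = (jp - jp.conj().T) / 2j
    lam, u = np.linalg.eigh(jy)
    return lam, u


_JY_EIG = _jy_rank2()


def wigner_d2(beta) -> np.ndarray:
    """Reduced rank-2 Wigner matrix d²_{m'm}(β), indices m = −2 … +2.

    Accepts scalar or array β (radians); trailing axes are (5, 5).
    """
    lam, u = _JY_EIG
    beta = np.asarray(beta, dtype=float)
    ph = np.exp(-1j * beta[..., None] * lam)
    return np.einsum("ik,...k,jk->...ij", u, ph, u.conj()).real


def wigner_D2(alpha, beta, gamma) -> np.ndarray:
    """Full rank-2 Wigner matrix D²_{m'm}(α,β,γ) = e^{−im'α} d²(β) e^{−imγ}."""
    alpha = np.asarray(alpha, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    d = wigner_d2(beta)
    return (
        np.exp(-1j * _M2 * alpha[..., None])[..., :, None]
        * d
        * np.exp(-1j * _M2 * gamma[..., None])[..., None, :]
    )


def wigner_rotate(components, euler) -> np.ndarray:
    """Actively rotate rank-2 spherical components by Euler angles (radians).

    ``A'_{m'} = Σ_m D²_{m'm}(α,β,γ) A_m``; preserves Σ|A_m|².
    """
    components = np.asarray(components, dtype=complex)
    if components.shape[-1] != 5:
        raise ValueError("expected five spherical components m = −2 … +2")
    D = wigner_D2(*euler)
    return np.einsum("...mn,...n->...m", D, components)


# ----------------------------------------------------------------------
# Spatial tensors (PAS components, rad/s)
# ----------------------------------------------------------------------

def quad_pas_components(q: QuadrupoleInteraction) -> np.ndarray:
    """Quadrupole spatial tensor in its PAS, rad/s, indices m = −2 … +2.

    ``A_{2,0} = √6·K`` and ``A_{2,±2} = −η·K`` with ``K = 2π·C_Q/4`` (the
    spin-1 scaling), so ``|A_{2,±2}/A_{2,0}| = η/√6``.
    """
    K = 2 * np.pi * q.cq_mhz * 1e6 / 4.0
    A = np.zeros(5, complex)
    A[2] = np.sqrt(6.0) * K
    A[0] = A[4] = -q.eta * K
    return A


def dipole_pas_components(d: DipolarInteraction) -> np.ndarray:
    """Dipolar spatial tensor in the dipolar PAS (axial), rad/s."""
    A = np.zeros(5, complex)
    A[2] = np.sqrt(6.0) * 2 * np.pi * d.coupling_khz * 1e3
    return A


def mas_fourier_coefficients(
    rotor_frame_components, mas_rate_khz: float, rotor_axis_angle_deg: float
) -> np.ndarray:
    """Fourier coefficients of the secular (lab m=0) spatial component.

    Returns c_m (m = −2 … +2) with ω(t) = Σ_m c_m e^{−i m ω_r t};
    ``c_m = d²_{0m}(θ_rotor) · A^rot_m``.  At the exact magic angle
    c_0 of a traceless tensor vanishes since d²₀₀(θ_m) = P₂(cosθ_m) = 0.
    """
    A = np.asarray(rotor_frame_components, dtype=complex)
    d = wigner_d2(np.radians(rotor_axis_angle_deg))
    return d[2, :] * A


# ----------------------------------------------------------------------
# Hamiltonian
# ----------------------------------------------------------------------

def _racah_stack(tensors: dict[int, np.ndarray]) -> np.ndarray:
    """Stack (−1)^m T_{2,−m} over m = −2 … +2 for Σ_m (−1)^m A_m T_{2,−m}."""
    return np.stack([(-1.0) ** int(m) * tensors[-int(m)] for m in _M2])


@lru_cache(maxsize=1)
def _coupling_stacks() -> tuple[np.ndarray, np.ndarray]:
    ops = pair_operators()
    # quadrupole: rank-2 on the spin-1 alone, embedded
    TQ = {m: embed(_racah_tensor(1.0, 2, m), SpinLabel.N14) for m in _M2}
    # dipole: bilinear rank-2 of the pair
    Iz, Ip, Im = ops.Iz, ops.Ip, ops.Im
    Sz, Sp, Sm = ops.Sz, ops.Sp, ops.Sm
    IdotS = ops.Ix @ ops.Sx + ops.Iy @ ops.Sy + Iz @ Sz
    TD = {
        0: (3 * Iz @ Sz - IdotS) / np.sqrt(6.0),
        1: -(Ip @ Sz + Iz @ Sp) / 2,
        -1: (Im @ Sz + Iz @ Sm) / 2,
        2: Ip @ Sp / 2,
        -2: Im @ Sm / 2,
    }
    return _racah_stack(TQ), _racah_stack(TD)


class HamiltonianGenerator:
    """Batched rotating-frame Hamiltonian H(t) for a set of crystallites.

    Parameters
    ----------
    system : SpinSystemSpec
    orientations_rad : (N, 3) array of crystallite Euler angles (radians)
        carrying the dipolar frame into the rotor frame.
    include_second_order : include the second-order diagonal corrections
        (quadrupole self-terms and quadrupole–dipole cross terms).
    include_first_order : include the first-order secular couplings.
    """

    def __init__(
        self,
        system: SpinSystemSpec,
        orientations_rad,
        *,
        include_second_order: bool = True,
        include_first_order: bool = True,
    ):
        self.system = system
        ori = np.atleast_2d(np.asarray(orientations_rad, dtype=float))
        if ori.shape[-1] != 3:
            raise ValueError("orientations must be (N, 3) Euler angles")
        self.n_orientations = ori.shape[0]
        self.include_second_order = include_second_order
        self.include_first_order = include_first_order

        f = system.fields
        if include_second_order and (f.larmor_14n_mhz <= 0 or f.larmor_13c_mhz <= 0):
            raise ValueError("second-order terms require positive Larmor frequencies")

        # PAS -> dipolar frame -> rotor frame
        euler = np.radians(system.quadrupole.euler_to_dipole_deg)
        if system.quadrupole.euler_sense == "dipole_to_quad":
            euler = (-euler[2], -euler[1], -euler[0])
        aq = wigner_rotate(quad_pas_components(system.quadrupole), euler)
        ad = dipole_pas_components(system.dipole)
        D = wigner_D2(ori[:, 0], ori[:, 1], ori[:, 2])
        self._aq_rot = np.einsum("bmn,n->bm", D, aq)
        self._ad_rot = np.einsum("bmn,n->bm", D, ad)

        self._d_rotor = wigner_d2(np.radians(f.rotor_axis_angle_deg))
        self._omega_r = 2 * np.pi * f.mas_rate_khz * 1e3

        ops = pair_operators()
        self._ops = ops
        # physical Zeeman energies (positive gyromagnetic ratios)
        e0 = -2 * np.pi * (
            f.larmor_13c_mhz * 1e6 * np.diag(ops.Sz).real
            + f.larmor_14n_mhz * 1e6 * np.diag(ops.Iz).real
        )
        den = e0[:, None] - e0[None, :]
        with np.errstate(divide="ignore"):
            inv = np.where(np.eye(6, dtype=bool), 0.0, 1.0 / np.where(den == 0, np.inf, den))
        self._inv_denominator = inv
        self._tq_stack, self._td_stack = _coupling_stacks()

        # static terms: J coupling and resonance offsets
        self._h_static = 2 * np.pi * system.dipole.j_hz * (ops.Iz @ ops.Sz)
        self._h_static = self._h_static - 2 * np.pi * 1e3 * (
            system.offset_n_khz * ops.Iz + system.offset_c_khz * ops.Sz
        )

    # -- spatial components -------------------------------------------------
    def lab_components(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Instantaneous lab-frame spherical components (N, 5) of the
        quadrupole and dipole tensors at time ``t`` (seconds)."""
        rot = self._d_rotor * np.exp(-1j * _M2 * self._omega_r * t)[None, :]
        return self._aq_rot @ rot.T, self._ad_rot @ rot.T

    def _rf_matrix(self, rf: Sequence[RfPulseSpec]) -> np.ndarray:
        ops = self._ops
        h = np.zeros((6, 6), complex)
        for p in rf:
            w1 = 2 * np.pi * p.nutation_khz * 1e3
            phi = np.radians(p.phase_deg)
            if p.channel is SpinLabel.N14:
                x, y, z = ops.Ix, ops.Iy, ops.Iz
            else:
                x, y, z = ops.Sx, ops.Sy, ops.Sz
            h = h + w1 * (np.cos(phi) * x + np.sin(phi) * y)
            # transmitter shifted from the main carrier acts as an extra
            # z-field during the pulse (offset-irradiation approximation)
            h = h + 2 * np.pi * p.offset_khz * 1e3 * z
        return h

    def secular_diagonal(self, t: float) -> np.ndarray:
        """Diagonal (N, 6) of the secular couplings at time ``t``:
        first-order terms plus, if enabled, the second-order static
        perturbation-theory corrections Σ_l |V_kl|²/(E⁰_k − E⁰_l)."""
        aq, ad = self.lab_components(t)
        V = np.einsum("bm,mij->bij", aq, self._tq_stack) + np.einsum(
            "bm,mij->bij", ad, self._td_stack
        )
        diag = np.zeros((self.n_orientations, 6))
        if self.include_first_order:
            diag += np.einsum("bii->bi", V).real
        if self.include_second_order:
            W = np.abs(V) ** 2
            np.einsum("bii->bi", W)[:] = 0.0
            diag += np.einsum("bkl,kl->bk", W, self._inv_denominator)
        return diag

    def hamiltonian(self, t: float, rf: Sequence[RfPulseSpec] = ()) -> np.ndarray:
        """Rotating-frame Hamiltonian (N, 6, 6), angular-frequency units."""
        diag = self.secular_diagonal(t)
        H = np.broadcast_to(
            self._rf_matrix(rf) + self._h_static, (self.n_orientations, 6, 6)
        ).copy()
        idx = np.arange(6)
        H[:, idx, idx] += diag
        return H


def hamiltonian_at(
    t: float,
    spec: SpinSystemSpec,
    orientation,
    rf: Iterable[RfPulseSpec] = (),
    *,
    include_second_order: bool = True,
    include_first_order: bool = True,
) -> np.ndarray:
    """Single-orientation rotating-frame Hamiltonian at time ``t`` (s)."""
    gen = HamiltonianGenerator(
        spec,
        np.asarray(orientation, dtype=float)[None, :],
        include_second_order=include_second_order,
        include_first_order=include_first_order,
    )
    return gen.hamiltonian(t, tuple(rf))[0]
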