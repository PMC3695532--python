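"""The indirect-detection experiment: ¹⁴N excitation pulse, coherence
selection, ¹³C π refocusing, t₁ evolution, reconversion, detection.

The sequence starts from unit ¹³C transverse magnetisation (the ideal
post-CP state; protons are outside the model).  A long rotor-synchronised
CW ¹⁴N pulse converts part of it into two-spin coherences of ¹⁴N order
p = ±1 (SQ) and ±2 (DQ); the desired orders are retained — by explicit
projection, or by an explicit phase cycle for cross-checking — evolve
freely for t₁ split symmetrically around an ideal ¹³C π pulse, and are
reconverted to observable ¹³C magnetisation by a second, identical ¹⁴N
pulse.  The reported efficiency is the magnitude of the powder-averaged
complex recovered transverse amplitude relative to the initial state.

With rotor-synchronised t₁ sampling the first-order quadrupolar phase
refocuses every increment, so the indirect dimension evolves only under
the second-order shifts and the resonance offset — disabling the
second-order terms on resonance freezes the indirect FID.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .interactions import RfPulseSpec, SpinSystemSpec
from .powder import PowderScheme, powder_average
from .propagation import PropagatorEngine, evolve
from .spin_algebra import SpinLabel, coherence_mask, pair_operators

__all__ = [
    "ExperimentSpec",
    "EfficiencyResult",
    "Hnc2DResult",
    "selection_orders",
    "run_hnc_1d",
    "run_hnc_2d",
    "phase_cycle_run",
    "coherence_amplitudes",
]

#: Frobenius norm of the initial deviation operator Sx
_RHO0_NORM = np.sqrt(1.5)
#: Tr(Sx · S⁻), normalisation of the detected transverse amplitude
_DETECT_NORM = 1.5


@dataclass(frozen=True)
class ExperimentSpec:
    """Experiment parameters of the indirect-detection sequence.

    ``tau_n_ms`` must equal an integer number of rotor periods; ``Δt₁``
    is ``dt1_rotor_periods`` rotor periods.  ``selection`` is "SQ", "DQ"
    or 0 (no filtering, echo reference).  2D detection is hypercomplex
    (States): a second data set is acquired with the reconversion-pulse
    phase shifted by 90°/|p|.
    """

    tau_n_ms: float = 2.0
    nu1_n_khz: float = 35.0
    offset_n_khz: float = 0.0
    offset_c_khz: float = 0.0
    phase_n_deg: float = 0.0
    mas_rate_khz: float | None = None  # None: use the system's field spec
    selection: str | int = "SQ"
    t1_increments: int = 1
    dt1_rotor_periods: int = 1

    def rf_pulse(self) -> RfPulseSpec:
        return RfPulseSpec(SpinLabel.N14, self.nu1_n_khz, self.phase_n_deg)


@dataclass(frozen=True)
class EfficiencyResult:
    """Outcome of a 1D run: recovered-signal ratio and the per-order
    ¹⁴N coherence amplitudes right after the excitation pulse."""

    efficiency: float
    signal: complex
    coherence_amplitudes: dict
    selection: str | int
    n_orientations: int
    tau_n_ms: float
    nu1_n_khz: float
    offset_n_khz: float = 0.0

    @property
    def sq_amplitude(self) -> float:
        """Combined p = ±1 amplitude, √(a₊₁² + a₋₁²)."""
        a = self.coherence_amplitudes
        return float(np.hypot(a[1], a[-1]))

    @property
    def dq_amplitude(self) -> float:
        a = self.coherence_amplitudes
        return float(np.hypot(a[2], a[-2]))


@dataclass(frozen=True)
class Hnc2DResult:
    """Hypercomplex indirect-dimension data: one complex ¹³C amplitude
    per t₁ point for the two States data sets."""

    t1_s: np.ndarray
    cos_signal: np.ndarray  # reconversion phase 0
    sin_signal: np.ndarray  # reconversion phase shifted by 90°/|p|
    dwell1_s: float
    selection: str | int
    efficiency_t1_0: float


def selection_orders(selection: str | int) -> tuple[int, ...]:
    """Map a selection label to the retained ¹⁴N coherence orders."""
    if isinstance(selection, str):
        key = selection.upper()
        if key == "SQ":
            return (-1, 1)
        if key == "DQ":
            return (-2, 2)
        raise ValueError(f"unknown selection {selection!r}; expected 'SQ', 'DQ' or an order")
    p = int(selection)
    if not 0 <= abs(p) <= 2:
        raise ValueError(f"coherence order {p} outside −2 … +2")
    return (0,) if p == 0 else (-p, p)


@lru_cache(maxsize=1)
def _pi_pulse_c() -> np.ndarray:
    """Ideal instantaneous π pulse on ¹³C about x: exp(−iπ Sx)."""
    ops = pair_operators()
    lam, V = np.linalg.eigh(ops.Sx)
    return (V * np.exp(-1j * np.pi * lam)) @ V.conj().T


def _rz_n(phi: float) -> np.ndarray:
    """z-rotation exp(−iφ Iz) on the ¹⁴N only."""
    ops = pair_operators()
    return np.diag(np.exp(-1j * phi * np.diag(ops.Iz).real))


def _n_rotor_periods(exp: ExperimentSpec, system: SpinSystemSpec) -> int:
    mas = exp.mas_rate_khz or system.fields.mas_rate_khz
    n = exp.tau_n_ms * mas
    if abs(n - round(n)) > 1e-6:
        raise ValueError(
            f"tau_n = {exp.tau_n_ms} ms is not rotor-synchronised at {mas} kHz MAS "
            f"({n:.3f} rotor periods)"
        )
    return int(round(n))


def _system_for(exp: ExperimentSpec, system: SpinSystemSpec) -> SpinSystemSpec:
    sys2 = system.with_offsets(
        offset_n_khz=system.offset_n_khz + exp.offset_n_khz,
        offset_c_khz=system.offset_c_khz + exp.offset_c_khz,
    )
    if exp.mas_rate_khz is not None and exp.mas_rate_khz != system.fields.mas_rate_khz:
        from dataclasses import replace

        sys2 = replace(sys2, fields=replace(sys2.fields, mas_rate_khz=exp.mas_rate_khz))
    return sys2


def build_engine(
    system: SpinSystemSpec,
    exp: ExperimentSpec,
    powder: PowderScheme,
    *,
    steps_per_period: int = 200,
    include_second_order: bool = True,
) -> PropagatorEngine:
    """Engine bound to the experiment's effective spin system and powder."""
    return PropagatorEngine(
        _system_for(exp, system),
        powder.orientations_rad,
        steps_per_period=steps_per_period,
        include_second_order=include_second_order,
    )


def _order_amplitudes_batched(rho: np.ndarray) -> dict[int, np.ndarray]:
    return {
        p: np.sqrt((np.abs(rho) ** 2 * coherence_mask(p)).sum(axis=(-2, -1))) / _RHO0_NORM
        for p in range(-2, 3)
    }


def coherence_amplitudes(rho_after_pulse: np.ndarray) -> dict[int, float]:
    """Per-order Frobenius amplitudes a_p = ‖ρ⁽ᵖ⁾‖/‖ρ₀‖ of a density
    operator, relative to the initial deviation state Sx.

    For unitary evolution of the pure deviation state, Σ_p a_p² = 1.
    """
    rho = np.asarray(rho_after_pulse, complex)
    if rho.ndim != 2:
        raise ValueError("expected a single 6×6 density operator")
    amps = _order_amplitudes_batched(rho)
    return {p: float(a) for p, a in amps.items()}


def _detect(rho: np.ndarray) -> np.ndarray:
    """Complex transverse ¹³C amplitude Tr(ρ S⁻)/Tr(ρ₀ S⁻) per orientation."""
    ops = pair_operators()
    return np.einsum("...ij,ji->...", rho, ops.Sm) / _DETECT_NORM


def run_hnc_1d(
    system: SpinSystemSpec,
    exp: ExperimentSpec,
    powder: PowderScheme,
    *,
    steps_per_period: int = 200,
    include_second_order: bool = True,
    engine: PropagatorEngine | None = None,
) -> EfficiencyResult:
    """One-dimensional ¹⁴N-filtered run (no t₁ evolution).

    Excitation pulse → projection onto the selected ¹⁴N coherence orders
    → ideal ¹³C π pulse → reconversion pulse → detection, powder-averaged.
    """
    n_per = _n_rotor_periods(exp, system)
    if engine is None:
        engine = build_engine(
            system, exp, powder,
            steps_per_period=steps_per_period,
            include_second_order=include_second_order,
        )
    ops = pair_operators()
    U = engine.pulse_propagator((exp.rf_pulse(),), n_per)
    rho1 = evolve(ops.Sx, U)
    amps = {p: float(powder_average(a, powder)) for p, a in _order_amplitudes_batched(rho1).items()}
    rho_f = rho1 * coherence_mask(*selection_orders(exp.selection))
    rho2 = evolve(rho_f, _pi_pulse_c())
    rho3 = evolve(rho2, U)
    signal = complex(powder_average(_detect(rho3), powder))
    return EfficiencyResult(
        efficiency=abs(signal),
        signal=signal,
        coherence_amplitudes=amps,
        selection=exp.selection,
        n_orientations=len(powder),
        tau_n_ms=exp.tau_n_ms,
        nu1_n_khz=exp.nu1_n_khz,
        offset_n_khz=exp.offset_n_khz,
    )


def run_hnc_2d(
    system: SpinSystemSpec,
    exp: ExperimentSpec,
    powder: PowderScheme,
    *,
    steps_per_period: int = 200,
    include_second_order: bool = True,
    engine: PropagatorEngine | None = None,
) -> Hnc2DResult:
    """Two-dimensional run: the selected ¹⁴N coherences evolve for t₁
    (integer rotor periods, split symmetrically around the π pulse) and
    two States data sets are recorded with 90°/|p|-shifted reconversion
    phase.  The t₁ = 0 column equals the 1D result."""
    if exp.t1_increments < 1:
        raise ValueError("t1_increments must be ≥ 1")
    if exp.dt1_rotor_periods < 1:
        raise ValueError("Δt₁ must be a positive integer number of rotor periods")
    n_per = _n_rotor_periods(exp, system)
    if engine is None:
        engine = build_engine(
            system, exp, powder,
            steps_per_period=steps_per_period,
            include_second_order=include_second_order,
        )
    ops = pair_operators()
    orders = selection_orders(exp.selection)
    p_max = max(1, max(abs(p) for p in orders))
    rf = (exp.rf_pulse(),)
    U = engine.pulse_propagator(rf, n_per)
    rz = _rz_n(-np.pi / (2 * p_max))
    U_shift = rz @ U @ rz.conj().T

    rho_f = evolve(ops.Sx, U) * coherence_mask(*orders)
    pi_c = _pi_pulse_c()

    tr = engine.rotor_period_s
    dt1 = exp.dt1_rotor_periods * tr
    t1 = np.arange(exp.t1_increments) * dt1
    cos_sig = np.zeros(exp.t1_increments, complex)
    sin_sig = np.zeros(exp.t1_increments, complex)
    for j in range(exp.t1_increments):
        halves = j * exp.dt1_rotor_periods  # each t₁/2 in half rotor periods
        seg1 = engine.segment_propagator(0, halves)
        seg2 = engine.segment_propagator(halves % 2, halves)
        rho_t = evolve(evolve(evolve(rho_f, seg1), pi_c), seg2)
        cos_sig[j] = powder_average(_detect(evolve(rho_t, U)), powder)
        sin_sig[j] = powder_average(_detect(evolve(rho_t, U_shift)), powder)
    return Hnc2DResult(
        t1_s=t1,
        cos_signal=cos_sig,
        sin_signal=sin_sig,
        dwell1_s=dt1,
        selection=exp.selection,
        efficiency_t1_0=float(abs(cos_sig[0])),
    )


def phase_cycle_run(
    system: SpinSystemSpec,
    exp: ExperimentSpec,
    powder: PowderScheme,
    n_phases: int,
    *,
    steps_per_period: int = 200,
    include_second_order: bool = True,
    engine: PropagatorEngine | None = None,
    allow_underresolved: bool = False,
) -> EfficiencyResult:
    """Coherence selection by an explicit phase cycle of the excitation
    pulse with receiver weighting, instead of projection.

    The excitation-pulse phase steps through φ_k = 2πk/n and the receiver
    applies weights (e^{+ipφ_k} + e^{−ipφ_k})/n, retaining orders ±p
    (mod n).  With n ≥ 2p+1 this reproduces the projection filter; an
    under-resolved cycle (allowed only explicitly) aliases other orders.
    """
    n_per = _n_rotor_periods(exp, system)
    orders = selection_orders(exp.selection)
    p_sel = max(abs(p) for p in orders)
    if n_phases < 2 * p_sel + 1 and not allow_underresolved:
        raise ValueError(
            f"{n_phases}-step cycle cannot isolate order ±{p_sel}; need ≥ {2 * p_sel + 1}"
        )
    if engine is None:
        engine = build_engine(
            system, exp, powder,
            steps_per_period=steps_per_period,
            include_second_order=include_second_order,
        )
    ops = pair_operators()
    U = engine.pulse_propagator((exp.rf_pulse(),), n_per)
    rho1 = evolve(ops.Sx, U)
    amps = {p: float(powder_average(a, powder)) for p, a in _order_amplitudes_batched(rho1).items()}
    pi_c = _pi_pulse_c()
    total = np.zeros(engine.n_orientations, complex)
    for k in range(n_phases):
        phi = 2 * np.pi * k / n_phases
        rz = _rz_n(phi)
        rho_k = np.einsum("ij,...jk,lk->...il", rz, rho1, rz.conj())
        rho3 = evolve(evolve(rho_k, pi_c), U)
        weight = (np.exp(1j * p_sel * phi) + np.exp(-1j * p_sel * phi)) / (
            2 * n_phases if p_sel == 0 else n_phases
        )
        total += weight * _detect(rho3)
    signal = complex(powder_average(total, powder))
    return EfficiencyResult(
        efficiency=abs(signal),
        signal=signal,
        coherence_amplitudes=amps,
        selection=exp.selection,
        n_orientations=len(powder),
        tau_n_ms=exp.tau_n_ms,
        nu1_n_khz=exp.nu1_n_khz,
        offset_n_khz=exp.offset_n_khz,
    )
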