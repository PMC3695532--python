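"""Parameter scans: efficiency versus pulse length, rf amplitude and
¹⁴N offset, and the pulse-length × rf-amplitude surface.

Pulse lengths are rotor-synchronised; requested values are snapped to
the nearest integer number of rotor periods (with a warning).  Results
are reported both raw and normalised to unit maximum, as in the
published efficiency maps.  Pulse-length scans reuse the single cached
rotor-period propagator, so the cost is dominated by one propagator
build per rf/offset setting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .powder import PowderScheme, powder_average
from .propagation import evolve, matrix_power_batched
from .sequence import (
    ExperimentSpec,
    _detect,
    _pi_pulse_c,
    build_engine,
    run_hnc_1d,
    selection_orders,
)
from .spin_algebra import coherence_mask, pair_operators
from .interactions import SpinSystemSpec

__all__ = ["ScanResult", "GridScanResult", "snap_tau", "scan_pulse_length", "scan_rf", "scan_offset", "grid_scan"]


@dataclass(frozen=True)
class ScanResult:
    """1D scan outcome; ``normalised`` has maximum exactly 1.0."""

    axis_values: np.ndarray
    axis_unit: str
    raw: np.ndarray
    normalised: np.ndarray
    argmax_value: float

    def band(self, level: float = 0.5) -> tuple[float, float]:
        """Extent (min, max) of axis values with normalised efficiency
        above ``level``."""
        sel = self.axis_values[self.normalised > level]
        if sel.size == 0:
            raise ValueError(f"no points above level {level}")
        return float(sel.min()), float(sel.max())


@dataclass(frozen=True)
class GridScanResult:
    """2D scan outcome over (rf amplitude, pulse length)."""

    tau_values_ms: np.ndarray
    nu1_values_khz: np.ndarray
    raw: np.ndarray  # shape (n_nu1, n_tau)
    normalised: np.ndarray
    argmax_nu1_khz: float
    argmax_tau_ms: float


def _finalise(axis, unit, raw) -> ScanResult:
    axis = np.asarray(axis, float)
    raw = np.asarray(raw, float)
    if raw.size == 0:
        raise ValueError("empty scan grid")
    peak = raw.max()
    norm = raw / peak if peak > 0 else raw.copy()
    return ScanResult(axis, unit, raw, norm, float(axis[int(raw.argmax())]))


def snap_tau(tau_ms: float, mas_rate_khz: float) -> float:
    """Snap a pulse length to the nearest integer number of rotor periods."""
    n = max(0, int(round(tau_ms * mas_rate_khz)))
    snapped = n / mas_rate_khz
    if abs(snapped - tau_ms) > 1e-9:
        warnings.warn(
            f"tau = {tau_ms} ms snapped to {snapped:.6g} ms "
            f"({n} rotor periods at {mas_rate_khz} kHz MAS)",
            stacklevel=2,
        )
    return snapped


def _tau_scan_efficiencies(
    system: SpinSystemSpec,
    exp: ExperimentSpec,
    n_periods: np.ndarray,
    powder: PowderScheme,
    *,
    steps_per_period: int,
    include_second_order: bool,
    engine=None,
) -> np.ndarray:
    """Efficiencies for a set of rotor-synchronised pulse lengths, reusing
    powers of the cached rotor-period propagator."""
    if engine is None:
        engine = build_engine(
            system, exp, powder,
            steps_per_period=steps_per_period,
            include_second_order=include_second_order,
        )
    ops = pair_operators()
    mask = coherence_mask(*selection_orders(exp.selection))
    pi_c = _pi_pulse_c()
    U_period = engine.period_propagator((exp.rf_pulse(),))
    out = np.zeros(len(n_periods))
    order = np.argsort(n_periods)
    U = matrix_power_batched(U_period, int(n_periods[order[0]]))
    prev = int(n_periods[order[0]])
    for idx in order:
        n = int(n_periods[idx])
        if n != prev:
            U = matrix_power_batched(U_period, n - prev) @ U
            prev = n
        rho3 = evolve(evolve(evolve(ops.Sx, U) * mask, pi_c), U)
        out[idx] = abs(powder_average(_detect(rho3), powder))
    return out


def scan_pulse_length(
    system: SpinSystemSpec,
    exp_template: ExperimentSpec,
    tau_values_ms,
    powder: PowderScheme,
    *,
    steps_per_period: int = 200,
    include_second_order: bool = True,
) -> ScanResult:
    """Efficiency versus ¹⁴N pulse duration (rotor-synchronised)."""
    tau_values_ms = np.asarray(tau_values_ms, float)
    if tau_values_ms.size == 0:
        raise ValueError("empty scan grid")
    mas = exp_template.mas_rate_khz or system.fields.mas_rate_khz
    snapped = np.array([snap_tau(t, mas) for t in tau_values_ms])
    n_periods = np.round(snapped * mas).astype(int)
    raw = _tau_scan_efficiencies(
        system, exp_template, n_periods, powder,
        steps_per_period=steps_per_period,
        include_second_order=include_second_order,
    )
    return _finalise(snapped, "ms", raw)


def scan_rf(
    system: SpinSystemSpec,
    exp_template: ExperimentSpec,
    nu1_values_khz,
    powder: PowderScheme,
    *,
    steps_per_period: int = 200,
    include_second_order: bool = True,
) -> ScanResult:
    """Efficiency versus ¹⁴N rf amplitude at fixed pulse length."""
    nu1_values_khz = np.asarray(nu1_values_khz, float)
    if nu1_values_khz.size == 0:
        raise ValueError("empty scan grid")
    mas = exp_template.mas_rate_khz or system.fields.mas_rate_khz
    exp_template = replace(exp_template, tau_n_ms=snap_tau(exp_template.tau_n_ms, mas))
    engine = build_engine(
        system, exp_template, powder,
        steps_per_period=steps_per_period,
        include_second_order=include_second_order,
    )
    raw = []
    for nu1 in nu1_values_khz:
        exp = replace(exp_template, nu1_n_khz=float(nu1))
        raw.append(run_hnc_1d(system, exp, powder, engine=engine).efficiency)
    return _finalise(nu1_values_khz, "kHz", raw)


def scan_offset(
    system: SpinSystemSpec,
    exp_template: ExperimentSpec,
    offset_values_khz,
    powder: PowderScheme,
    *,
    steps_per_period: int = 200,
    include_second_order: bool = True,
) -> ScanResult:
    """Efficiency versus ¹⁴N resonance offset (site minus carrier)."""
    offset_values_khz = np.asarray(offset_values_khz, float)
    if offset_values_khz.size == 0:
        raise ValueError("empty scan grid")
    mas = exp_template.mas_rate_khz or system.fields.mas_rate_khz
    exp_template = replace(exp_template, tau_n_ms=snap_tau(exp_template.tau_n_ms, mas))
    raw = []
    for off in offset_values_khz:
        exp = replace(exp_template, offset_n_khz=float(off))
        raw.append(
            run_hnc_1d(
                system, exp, powder,
                steps_per_period=steps_per_period,
                include_second_order=include_second_order,
            ).efficiency
        )
    return _finalise(offset_values_khz, "kHz", raw)


def grid_scan(
    system: SpinSystemSpec,
    exp_template: ExperimentSpec,
    tau_values_ms,
    nu1_values_khz,
    powder: PowderScheme,
    *,
    steps_per_period: int = 200,
    include_second_order: bool = True,
) -> GridScanResult:
    """Efficiency surface over pulse length × rf amplitude."""
    tau_values_ms = np.asarray(tau_values_ms, float)
    nu1_values_khz = np.asarray(nu1_values_khz, float)
    if tau_values_ms.size == 0 or nu1_values_khz.size == 0:
        raise ValueError("empty scan grid")
    mas = exp_template.mas_rate_khz or system.fields.mas_rate_khz
    snapped = np.array([snap_tau(t, mas) for t in tau_values_ms])
    n_periods = np.round(snapped * mas).astype(int)
    engine = build_engine(
        system, exp_template, powder,
        steps_per_period=steps_per_period,
        include_second_order=include_second_order,
    )
    raw = np.zeros((len(nu1_values_khz), len(snapped)))
    for i, nu1 in enumerate(nu1_values_khz):
        exp = replace(exp_template, nu1_n_khz=float(nu1))
        raw[i] = _tau_scan_efficiencies(
            system, exp, n_periods, powder,
            steps_per_period=steps_per_period,
            include_second_order=include_second_order,
            engine=engine,
        )
    peak = raw.max()
    norm = raw / peak if peak > 0 else raw.copy()
    i, j = np.unravel_index(int(raw.argmax()), raw.shape)
    return GridScanResult(
        tau_values_ms=snapped,
        nu1_values_khz=nu1_values_khz,
        raw=raw,
        normalised=norm,
        argmax_nu1_khz=float(nu1_values_khz[i]),
        argmax_tau_ms=float(snapped[j]),
    )
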