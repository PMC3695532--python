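"""Configuration files, named presets and result serialization.

Config files are YAML with unit-suffixed keys (``cq_mhz``, ``nu1_n_khz``,
…) so MHz/kHz mix-ups are caught by eye.  The two parameter sets used in
the published simulations ship as presets:

* ``glycine_amine`` — C_Q 1.18 MHz, η 0.54, dipole −0.716 kHz, EFG
  collinear with the dipolar vector (amine/NH₃⁺ geometry);
* ``triglycine_amide`` — C_Q 3.01 MHz, η 0.48, dipole −0.928 kHz, EFG at
  (0°, 90°, 120°) to the dipolar frame (peptide amide geometry).

Outputs are JSON (scalars, metadata) and delimited text (tables), with a
config echo and the package version for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .interactions import (
    MAGIC_ANGLE_DEG,
    DipolarInteraction,
    FieldSpec,
    QuadrupoleInteraction,
    SpinSystemSpec,
)
from .scans import GridScanResult, ScanResult
from .sequence import EfficiencyResult, ExperimentSpec, Hnc2DResult
from .spectra import Spectrum, Spectrum2D

__all__ = ["PRESETS", "preset_system", "RunConfig", "load_config", "write_results"]


def _preset(cq, eta, euler, dip) -> SpinSystemSpec:
    return SpinSystemSpec(
        quadrupole=QuadrupoleInteraction(cq_mhz=cq, eta=eta, euler_to_dipole_deg=euler),
        dipole=DipolarInteraction(coupling_khz=dip),
        fields=FieldSpec(),
    )


PRESETS: dict[str, SpinSystemSpec] = {
    "glycine_amine": _preset(1.18, 0.54, (0.0, 0.0, 0.0), -0.716),
    "triglycine_amide": _preset(3.01, 0.48, (0.0, 90.0, 120.0), -0.928),
}


def preset_system(name: str) -> SpinSystemSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


@dataclass(frozen=True)
class ProcessingSpec:
    lb_hz: float = 30.0
    lb1_hz: float = 0.0
    zerofill: int = 1024


@dataclass(frozen=True)
class RunConfig:
    """Fully validated run configuration."""

    system: SpinSystemSpec
    experiment: ExperimentSpec
    powder_size: int = 1154
    processing: ProcessingSpec = field(default_factory=ProcessingSpec)
    steps_per_period: int = 200
    include_second_order: bool = True
    output_dir: str = "quadspy_results"
    preset: str | None = None

    def to_dict(self) -> dict:
        sys_d = {
            "cq_mhz": self.system.quadrupole.cq_mhz,
            "eta": self.system.quadrupole.eta,
            "euler_qd_deg": list(self.system.quadrupole.euler_to_dipole_deg),
            "dipole_khz": self.system.dipole.coupling_khz,
            "j_hz": self.system.dipole.j_hz,
            "larmor_13c_mhz": self.system.fields.larmor_13c_mhz,
            "larmor_14n_mhz": self.system.fields.larmor_14n_mhz,
            "mas_rate_khz": self.system.fields.mas_rate_khz,
            "rotor_axis_angle_deg": self.system.fields.rotor_axis_angle_deg,
        }
        if self.preset:
            sys_d["preset"] = self.preset
        exp = self.experiment
        return {
            "system": sys_d,
            "experiment": {
                "tau_n_ms": exp.tau_n_ms,
                "nu1_n_khz": exp.nu1_n_khz,
                "offset_n_khz": exp.offset_n_khz,
                "offset_c_khz": exp.offset_c_khz,
                "selection": exp.selection,
                "t1_increments": exp.t1_increments,
                "dt1_rotor_periods": exp.dt1_rotor_periods,
            },
            "powder": {"size": self.powder_size},
            "processing": {
                "lb_hz": self.processing.lb_hz,
                "lb1_hz": self.processing.lb1_hz,
                "zerofill": self.processing.zerofill,
            },
            "simulation": {
                "steps_per_period": self.steps_per_period,
                "include_second_order": self.include_second_order,
            },
            "output_dir": self.output_dir,
        }

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _take(d: dict, section: str, allowed: set[str]) -> dict:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in '{section}': {', '.join(sorted(unknown))}")
    return d


def _build_system(d: dict) -> tuple[SpinSystemSpec, str | None]:
    _take(
        d,
        "system",
        {
            "preset", "cq_mhz", "eta", "euler_qd_deg", "dipole_khz", "j_hz",
            "larmor_13c_mhz", "larmor_14n_mhz", "mas_rate_khz", "rotor_axis_angle_deg",
        },
    )
    preset = d.get("preset")
    if preset is not None:
        system = preset_system(preset)
        quad, dip = system.quadrupole, system.dipole
    else:
        for key in ("cq_mhz", "eta", "dipole_khz"):
            if key not in d:
                raise ValueError(f"system: missing required field '{key}' (or use a preset)")
        quad = QuadrupoleInteraction(
            cq_mhz=float(d["cq_mhz"]),
            eta=float(d["eta"]),
            euler_to_dipole_deg=tuple(d.get("euler_qd_deg", (0.0, 0.0, 0.0))),
        )
        dip = DipolarInteraction(coupling_khz=float(d["dipole_khz"]), j_hz=float(d.get("j_hz", 0.0)))
    if preset is not None:
        quad = replace(quad, cq_mhz=float(d.get("cq_mhz", quad.cq_mhz)), eta=float(d.get("eta", quad.eta)))
        dip = replace(dip, coupling_khz=float(d.get("dipole_khz", dip.coupling_khz)), j_hz=float(d.get("j_hz", dip.j_hz)))
    if "mas_rate_khz" not in d:
        raise ValueError("system: missing required field 'mas_rate_khz'")
    fields = FieldSpec(
        larmor_13c_mhz=float(d.get("larmor_13c_mhz", 150.0)),
        larmor_14n_mhz=float(d.get("larmor_14n_mhz", 43.5)),
        mas_rate_khz=float(d["mas_rate_khz"]),
        rotor_axis_angle_deg=float(d.get("rotor_axis_angle_deg", MAGIC_ANGLE_DEG)),
    )
    return SpinSystemSpec(quadrupole=quad, dipole=dip, fields=fields), preset


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected and missing required fields raise errors
    naming the field.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    _take(raw, "top level", {"system", "experiment", "powder", "processing", "simulation", "output_dir"})
    if "system" not in raw:
        raise ValueError("config: missing 'system' section")
    system, preset = _build_system(dict(raw["system"]))

    e = dict(raw.get("experiment", {}))
    _take(
        e,
        "experiment",
        {"tau_n_ms", "nu1_n_khz", "offset_n_khz", "offset_c_khz", "selection",
         "t1_increments", "dt1_rotor_periods"},
    )
    experiment = ExperimentSpec(
        tau_n_ms=float(e.get("tau_n_ms", 2.0)),
        nu1_n_khz=float(e.get("nu1_n_khz", 35.0)),
        offset_n_khz=float(e.get("offset_n_khz", 0.0)),
        offset_c_khz=float(e.get("offset_c_khz", 0.0)),
        selection=e.get("selection", "SQ"),
        t1_increments=int(e.get("t1_increments", 1)),
        dt1_rotor_periods=int(e.get("dt1_rotor_periods", 1)),
    )

    p = dict(raw.get("powder", {}))
    _take(p, "powder", {"size"})
    powder_size = int(p.get("size", 1154))

    pr = dict(raw.get("processing", {}))
    _take(pr, "processing", {"lb_hz", "lb1_hz", "zerofill"})
    processing = ProcessingSpec(
        lb_hz=float(pr.get("lb_hz", 30.0)),
        lb1_hz=float(pr.get("lb1_hz", 0.0)),
        zerofill=int(pr.get("zerofill", 1024)),
    )

    sim = dict(raw.get("simulation", {}))
    _take(sim, "simulation", {"steps_per_period", "include_second_order"})
    return RunConfig(
        system=system,
        experiment=experiment,
        powder_size=powder_size,
        processing=processing,
        steps_per_period=int(sim.get("steps_per_period", 200)),
        include_second_order=bool(sim.get("include_second_order", True)),
        output_dir=str(raw.get("output_dir", "quadspy_results")),
        preset=preset,
    )


# ----------------------------------------------------------------------
# result serialization
# ----------------------------------------------------------------------

def _meta(config: RunConfig | None) -> dict:
    out = {"software": "quadspy", "version": __version__}
    if config is not None:
        out["config"] = config.to_dict()
    return out


def _write_csv(path: Path, header_lines: list[str], columns: dict[str, np.ndarray]) -> None:
    names = list(columns)
    data = np.column_stack([np.asarray(columns[n]) for n in names])
    header = "\n".join(header_lines + [",".join(names)])
    np.savetxt(path, data, delimiter=",", header=header, comments="# ")


def write_results(result, out_dir, *, config: RunConfig | None = None, stem: str | None = None) -> list[Path]:
    """Serialize a result object to ``out_dir``; returns the files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def jdump(name: str, payload: dict) -> None:
        path = out / name
        path.write_text(json.dumps({**payload, "provenance": _meta(config)}, indent=2))
        written.append(path)

    if isinstance(result, EfficiencyResult):
        jdump((stem or "efficiency") + ".json", {
            "efficiency": result.efficiency,
            "signal_real": result.signal.real,
            "signal_imag": result.signal.imag,
            "coherence_amplitudes": {str(p): a for p, a in result.coherence_amplitudes.items()},
            "sq_amplitude": result.sq_amplitude,
            "dq_amplitude": result.dq_amplitude,
            "selection": str(result.selection),
            "n_orientations": result.n_orientations,
            "tau_n_ms": result.tau_n_ms,
            "nu1_n_khz": result.nu1_n_khz,
        })
    elif isinstance(result, ScanResult):
        path = out / ((stem or "scan") + ".csv")
        _write_csv(
            path,
            [f"quadspy {__version__} scan; axis unit: {result.axis_unit}",
             f"argmax: {result.argmax_value} {result.axis_unit}"],
            {f"axis_{result.axis_unit}": result.axis_values,
             "efficiency": result.raw,
             "normalised": result.normalised},
        )
        written.append(path)
    elif isinstance(result, GridScanResult):
        path = out / ((stem or "grid") + ".csv")
        nu1, tau = np.meshgrid(result.nu1_values_khz, result.tau_values_ms, indexing="ij")
        _write_csv(
            path,
            [f"quadspy {__version__} grid scan",
             f"argmax: nu1 = {result.argmax_nu1_khz} kHz, tau = {result.argmax_tau_ms} ms"],
            {"nu1_khz": nu1.ravel(), "tau_ms": tau.ravel(),
             "efficiency": result.raw.ravel(), "normalised": result.normalised.ravel()},
        )
        written.append(path)
    elif isinstance(result, Hnc2DResult):
        path = out / ((stem or "fid2d") + ".csv")
        _write_csv(
            path,
            [f"quadspy {__version__} hypercomplex indirect FID (States)"],
            {"t1_s": result.t1_s,
             "cos_real": result.cos_signal.real, "cos_imag": result.cos_signal.imag,
             "sin_real": result.sin_signal.real, "sin_imag": result.sin_signal.imag},
        )
        written.append(path)
    elif isinstance(result, Spectrum):
        path = out / ((stem or "spectrum") + ".csv")
        cols = {"freq_khz": result.freq_khz, "intensity": result.intensity}
        if result.ppm is not None:
            cols["ppm"] = result.ppm
        _write_csv(path, [f"quadspy {__version__} spectrum; lb = {result.lb_hz} Hz"], cols)
        written.append(path)
    elif isinstance(result, Spectrum2D):
        path = out / ((stem or "spectrum2d") + ".csv")
        f1, f2 = np.meshgrid(result.freq1_khz, result.freq2_khz, indexing="ij")
        cols = {"freq1_khz": f1.ravel(), "freq2_khz": f2.ravel(),
                "intensity": result.intensity.ravel()}
        if result.ppm1 is not None:
            cols["ppm1"] = np.meshgrid(result.ppm1, result.freq2_khz, indexing="ij")[0].ravel()
        _write_csv(path, [f"quadspy {__version__} 2D spectrum"], cols)
        written.append(path)
    else:
        raise TypeError(f"cannot serialize result of type {type(result).__name__}")
    return written
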