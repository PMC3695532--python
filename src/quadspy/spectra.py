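"""Spectral processing: apodisation, zero-filling, FFT, hypercomplex
(States) 2D recombination, ppm axes and slice extraction.

Line broadening is exponential, ``exp(−π·lb·t)``, which produces a
Lorentzian of full width at half maximum equal to ``lb`` Hz.  ¹⁴N ppm
values are referenced to crystalline ammonium chloride at 35.9 ppm: a
signal at frequency offset f (Hz) from the NH₄Cl carrier appears at
``35.9 + f/ν₀`` ppm with ν₀ the ¹⁴N Larmor frequency in MHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interactions import FieldSpec
from .spin_algebra import SpinLabel

__all__ = [
    "N14_REFERENCE_PPM",
    "DEFAULT_ZEROFILL",
    "Spectrum",
    "Spectrum2D",
    "process_1d",
    "process_2d_states",
    "to_ppm",
    "extract_slice",
]

#: ¹⁴N shift of crystalline NH₄Cl, the reference compound
N14_REFERENCE_PPM = 35.9
#: default zero-fill length per dimension
DEFAULT_ZEROFILL = 1024


@dataclass(frozen=True)
class Spectrum:
    """1D spectrum: intensities over a frequency axis in kHz, with an
    optional ppm axis and the processing parameters used."""

    freq_khz: np.ndarray
    intensity: np.ndarray
    ppm: np.ndarray | None = None
    channel: SpinLabel | None = None
    lb_hz: float = 0.0
    zerofill: int = DEFAULT_ZEROFILL
    complex_intensity: np.ndarray | None = None


@dataclass(frozen=True)
class Spectrum2D:
    """2D spectrum with indirect (axis 0) and direct (axis 1) frequency
    axes in kHz."""

    freq1_khz: np.ndarray
    freq2_khz: np.ndarray
    intensity: np.ndarray
    ppm1: np.ndarray | None = None
    ppm2: np.ndarray | None = None
    lb_hz: float = 0.0


def _apodise(fid: np.ndarray, dwell_s: float, lb_hz: float, axis: int = -1) -> np.ndarray:
    if lb_hz == 0.0:
        return np.asarray(fid, complex)
    n = fid.shape[axis]
    t = np.arange(n) * dwell_s
    win = np.exp(-np.pi * lb_hz * t)
    shape = [1] * fid.ndim
    shape[axis] = n
    return np.asarray(fid, complex) * win.reshape(shape)


def _transform(fid: np.ndarray, dwell_s: float, zerofill: int, axis: int = -1):
    """Zero-fill, FFT (first point halved against baseline offset) and a
    shifted frequency axis in Hz, centred on the carrier."""
    fid = np.asarray(fid, complex)
    n = fid.shape[axis]
    if zerofill < n:
        raise ValueError(f"zero-fill length {zerofill} shorter than the FID ({n})")
    fid = fid.copy()
    first = [slice(None)] * fid.ndim
    first[axis] = slice(0, 1)
    fid[tuple(first)] *= 0.5
    spec = np.fft.fftshift(np.fft.fft(fid, n=zerofill, axis=axis), axes=axis)
    freq_hz = np.fft.fftshift(np.fft.fftfreq(zerofill, d=dwell_s))
    return spec, freq_hz


def process_1d(
    fid,
    dwell_s: float,
    lb_hz: float = 30.0,
    zerofill: int = DEFAULT_ZEROFILL,
    *,
    channel: SpinLabel | None = None,
    fields: FieldSpec | None = None,
    carrier_ppm: float = N14_REFERENCE_PPM,
) -> Spectrum:
    """Process a complex FID: exponential apodisation, zero-fill, FFT.

    Returns the real part as ``intensity`` (the full complex spectrum is
    kept alongside); if ``channel``/``fields`` are given, a ppm axis is
    attached with the carrier at ``carrier_ppm``.
    """
    fid = np.atleast_1d(np.asarray(fid, complex))
    if fid.size == 0:
        raise ValueError("empty FID")
    spec, freq_hz = _transform(_apodise(fid, dwell_s, lb_hz), dwell_s, zerofill)
    ppm = None
    if channel is not None and fields is not None:
        ppm = to_ppm(freq_hz / 1e3, channel, fields, carrier_ppm=carrier_ppm)
    return Spectrum(
        freq_khz=freq_hz / 1e3,
        intensity=spec.real,
        ppm=ppm,
        channel=channel,
        lb_hz=lb_hz,
        zerofill=zerofill,
        complex_intensity=spec,
    )


def process_2d_states(
    cos_table,
    sin_table,
    dwell1_s: float,
    dwell2_s: float | None = None,
    lb1_hz: float = 0.0,
    lb2_hz: float = 30.0,
    zerofill: int = DEFAULT_ZEROFILL,
    *,
    fields: FieldSpec | None = None,
    carrier_ppm: float = N14_REFERENCE_PPM,
) -> Spectrum2D:
    """Hypercomplex (States) processing of the indirect dimension.

    ``cos_table`` and ``sin_table`` are the two interleaved data sets
    (t₁ along axis 0; a direct-dimension axis 1 is optional).  The real
    parts are recombined into ``Re(cos) + i·Re(sin)`` giving a pure
    absorption, sign-discriminated indirect dimension of spectral width
    1/Δt₁.  If a direct dimension is present (and ``dwell2_s`` given) it
    is Fourier transformed with ``lb2_hz`` broadening.
    """
    cos_t = np.atleast_2d(np.asarray(cos_table, complex))
    sin_t = np.atleast_2d(np.asarray(sin_table, complex))
    if cos_t.shape != sin_t.shape:
        raise ValueError(f"shape mismatch: {cos_t.shape} vs {sin_t.shape}")
    hyper = cos_t.real + 1j * sin_t.real
    if cos_t.shape[1] > 1:
        if dwell2_s is None:
            raise ValueError("dwell2_s required for a sampled direct dimension")
        hyper, freq2_hz = _transform(
            _apodise(hyper, dwell2_s, lb2_hz, axis=1), dwell2_s, zerofill, axis=1
        )
    else:
        freq2_hz = np.zeros(cos_t.shape[1])
    spec, freq1_hz = _transform(_apodise(hyper, dwell1_s, lb1_hz, axis=0), dwell1_s, zerofill, axis=0)
    ppm1 = None
    if fields is not None:
        ppm1 = to_ppm(freq1_hz / 1e3, SpinLabel.N14, fields, carrier_ppm=carrier_ppm)
    return Spectrum2D(
        freq1_khz=freq1_hz / 1e3,
        freq2_khz=freq2_hz / 1e3,
        intensity=spec.real,
        ppm1=ppm1,
        lb_hz=lb2_hz,
    )


def to_ppm(
    freq_khz,
    channel: SpinLabel,
    fields: FieldSpec,
    *,
    carrier_ppm: float | None = None,
) -> np.ndarray:
    """Convert frequency offsets (kHz from the carrier) to ppm.

    For ¹⁴N the carrier defaults to the NH₄Cl reference at 35.9 ppm; for
    ¹³C it defaults to 0 ppm (no reference compound is modelled).
    """
    if channel is SpinLabel.N14:
        larmor_mhz = fields.larmor_14n_mhz
        ref = N14_REFERENCE_PPM if carrier_ppm is None else carrier_ppm
    elif channel is SpinLabel.C13:
        larmor_mhz = fields.larmor_13c_mhz
        ref = 0.0 if carrier_ppm is None else carrier_ppm
    else:  # pragma: no cover
        raise ValueError(f"unknown channel {channel!r}")
    return ref + np.asarray(freq_khz, float) * 1e3 / larmor_mhz


def extract_slice(spectrum: Spectrum2D, direct_position_khz: float) -> np.ndarray:
    """1D indirect-dimension trace through the direct-axis column nearest
    to ``direct_position_khz``, normalised to unit maximum."""
    f2 = spectrum.freq2_khz
    if not (f2.min() - 1e-9 <= direct_position_khz <= f2.max() + 1e-9):
        raise ValueError(
            f"direct position {direct_position_khz} kHz outside axis "
            f"[{f2.min()}, {f2.max()}]"
        )
    col = int(np.argmin(np.abs(f2 - direct_position_khz)))
    trace = spectrum.intensity[:, col]
    peak = np.max(np.abs(trace))
    return trace / peak if peak > 0 else trace.copy()
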