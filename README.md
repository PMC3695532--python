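# quadspy

Exact two-spin simulation of **indirect ¹⁴N detection in magic-angle
spinning (MAS) NMR through a ¹³C "spy" nucleus**.

¹⁴N is nature's nitrogen (99.6% abundant) but is a spin-1 nucleus with
quadrupolar couplings of a few MHz, which makes direct detection hard.
A practical alternative is an HMQC-type experiment in which ¹³C
transverse magnetisation is transferred to ¹⁴N single- or double-quantum
coherence by a **long (ms), moderate-amplitude (tens of kHz), continuous,
rotor-synchronised ¹⁴N pulse**, allowed to evolve, and transferred back
for ¹³C detection.  The transfer is mediated by the second-order
quadrupole–dipole cross terms (residual dipolar splittings) that survive
MAS.  quadspy simulates this experiment exactly for one ¹³C–¹⁴N pair, so
that efficiency maps (pulse length × rf amplitude × offset) and
second-order ¹⁴N lineshapes can be computed at desk scale.  It is aimed
at solid-state NMR spectroscopists setting up or interpreting ¹⁴N
indirect-detection experiments on organic and biomolecular solids.

## Model

For the coupled spin-1/2 ⊗ spin-1 pair the rotating-frame Hamiltonian is

```
H(t) = H_Q¹(t) + H_Q²(t) + H_QD²(t) + H_D(t) + H_J + H_rf + H_offsets
```

* `H_Q¹` — first-order secular quadrupole, ∝ C_Q·(3I_z² − I²), MHz scale,
  MAS-modulated through the rank-2 Wigner frame chain
  (quadrupole PAS → dipolar frame → crystallite → rotor → lab);
* `H_Q²`, `H_QD²` — second-order corrections from instantaneous static
  perturbation theory at each time step: exact Rayleigh–Schrödinger
  energies Σ|V_kl|²/(E⁰_k − E⁰_l) on the six Zeeman levels, giving the
  quadrupole self-shifts (∝ ω_Q²/ω₀, the anisotropic second-order
  lineshape) and the quadrupole–dipole cross terms that drive the
  ¹³C ↔ ¹⁴N transfer;
* `H_D` — secular heteronuclear dipole coupling 2I_zS_z with its MAS time
  dependence; `H_J` — scalar coupling;
* `H_rf` — CW ¹⁴N irradiation ν₁(I_x cosφ + I_y sinφ) plus offsets.

The density operator starts as Sₓ (ideal post-CP ¹³C magnetisation;
protons are outside the model), is propagated by exact piecewise-constant
unitaries (200 midpoint steps per rotor period by default, with
rotor-period caching `U(nτ_r) = U(τ_r)ⁿ`), filtered to the selected ¹⁴N
coherence orders (projection, or an explicit phase cycle as a
cross-check), refocused by an ideal ¹³C π pulse and reconverted by a
second identical pulse.  Powder averaging uses deterministic three-angle
ZCW orientation sets (the published simulations used the 6044-point set).
2D spectra are acquired rotor-synchronously (Δt₁ = nτ_r) with States
(hypercomplex) detection, so the indirect dimension shows the pure
second-order ¹⁴N lineshape.

## Worked example

The published working point for glycine: 1.18 MHz quadrupole (η = 0.54),
−716 Hz ¹³C–¹⁴N dipole coupling, 25 kHz MAS, a 2 ms ¹⁴N pulse at 35 kHz:

```python
import quadspy as q

glycine = q.preset_system("glycine_amine")
exp = q.ExperimentSpec(tau_n_ms=2.0, nu1_n_khz=35.0, selection="SQ")
powder = q.zcw_set(1154)

res = q.run_hnc_1d(glycine, exp, powder)
print(f"SQ coherence after the pulse: {res.sq_amplitude:.3f}")
print(f"recovered 13C signal:         {res.efficiency:.3f}")
```

prints

```
SQ coherence after the pulse: 0.366
recovered 13C signal:         0.190
```

i.e. the 2 ms pulse converts 37% of the initial ¹³C magnetisation norm
into ¹⁴N single-quantum coherence — well in excess of the 20% level that
makes the experiment practical — and 19% survives the full
filter/refocus/reconvert echo.  `res.coherence_amplitudes` holds the full
order-resolved breakdown (here a₀ = 0.83, a±₁ = 0.26, a±₂ = 0.18).

The same run from the shell, plus a parameter scan:

```bash
quadspy simulate examples/glycine.yaml
quadspy scan-rf examples/glycine.yaml --start 10 --stop 100 --step 5
quadspy reproduce fig5b          # amide pulse-length × rf-amplitude map
```

Scans write CSV tables (axis, raw efficiency, efficiency normalised to
unit maximum) with the argmax in the header; `simulate` writes a JSON
record with the efficiency, the per-order coherence amplitudes and a
config echo for provenance.

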