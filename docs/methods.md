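# Methods

## The physical model

quadspy simulates one ¹³C–¹⁴N spin pair (spin-1/2 ⊗ spin-1, a
6-dimensional Hilbert space) under magic-angle spinning.  The experiment
it models is an HMQC-type indirect-detection sequence: starting from
ideal ¹³C transverse magnetisation Sₓ, a long continuous ¹⁴N pulse of
`n` rotor periods generates two-spin coherences carrying ¹⁴N order
p = ±1 (SQ) and ±2 (DQ); the selected orders evolve for a
rotor-synchronised t₁ split symmetrically around an ideal ¹³C π pulse,
and an identical second pulse reconverts them to observable ¹³C
magnetisation.  Protons, cross-polarisation dynamics, relaxation and
¹³C chemical-shift anisotropy are deliberately outside the model: CP is
replaced by the ideal initial Sₓ state, and the π pulse refocuses ¹³C
shifts exactly (asserted by a test).  Consequently the efficiencies the
package reports are coherence-transfer efficiencies of the isolated
pair, not the experimentally observed ratios versus cross-polarisation,
which depend on proton decoupling and T₂.

### Hamiltonian

All interactions are carried as rank-2 spherical tensors through an
active-ZYZ Wigner chain

    quadrupole PAS →(preset Euler angles)→ dipolar PAS
                   →(crystallite angles)→ rotor frame
                   →(0, θ_rotor, ω_r t)→ lab frame,

with components indexed m = −2…+2 and
`A'_{m'} = Σ_m D²_{m'm}(Ω) A_m`, `D²_{m'm} = e^{−im'α} d²_{m'm}(β) e^{−imγ}`.
The quadrupole PAS components are `A₂₀ = √6·K`, `A₂±₂ = −η·K` with
`K = 2πC_Q/4` (spin-1 scaling).  With these conventions a static
crystallite at Euler angles (α, β, γ) has first-order SQ frequencies
`±(3C_Q/8)(3cos²β − 1 − η sin²β cos2γ)`, which the tests verify
pointwise against the Hamiltonian eigenvalues.  The sign choice for
A₂±₂ (equivalent to a 90° rotation of the EFG frame about its z axis)
is immaterial for the collinear amine preset; for the amide preset,
where the quadrupole sits at (0°, 90°, 120°) to the dipolar frame, it is
a documented convention.  The same applies to the direction of that
Euler rotation (quadrupole→dipole here): only a lineshape comparison
against a known sample discriminates the two readings, so the
alternative (inverse) reading is exposed as
`QuadrupoleInteraction.euler_sense = "dipole_to_quad"` rather than
hard-wired.

Second-order terms are obtained by **instantaneous static perturbation
theory**: at each time step the full coupling matrix V(t) (quadrupole +
dipole, all five spherical components) is assembled in the lab frame and
the secular (diagonal, in the heteronuclear Zeeman basis) correction
`Σ_{l≠k} |V_kl|² / (E⁰_k − E⁰_l)` is added to the first-order diagonal.
This single expression contains both the quadrupole self-terms (the
anisotropic and isotropic second-order shifts, ∝ ω_Q²/ω₀N) and the
quadrupole–dipole cross terms (residual dipolar splittings, with mixed
¹³C/¹⁴N denominators).  It is the standard "quadrupole to second order"
treatment, valid for ω_Q ≪ ω₀ (here 3 MHz versus 43.5 MHz); the
quasi-static evaluation is valid for ω_r ≪ ω₀.  Zeeman energies are
taken as −(ω₀S m_S + ω₀I m_I) (both gyromagnetic ratios positive), which
makes the spin-1 SQ second-order shift deshielding; its isotropic part
reproduces the closed form +(3/40)(C_Q²/ν₀)(1 + η²/3) to 0.05% in the
tests, and the full treatment was validated during development against
brute-force lab-frame propagation (Zeeman + untruncated rank-2 couplings
+ linearly polarised rf, sub-nanosecond steps): per-order coherence
amplitudes after a quarter-millisecond MAS pulse agree to a few percent
relative, confirming that neglected third-order and pulse–quadrupole
cross terms are small at these field strengths.

A resonance offset Δ (site minus carrier, positive = higher ppm) enters
as −2πΔ·I_z.  The model reproduces the experimentally reported
two-peaked offset-efficiency profile, with a sharp null where the
carrier coincides with the *apparent* (second-order shifted) line — the
effective z detuning is what drives the transfer, and on-resonance
transfer vanishes entirely when second-order terms are disabled (a test
asserts this).

### Propagation

H(t) is rotor-periodic under CW irradiation, so a pulse of n rotor
periods is propagated as `U(nτ_r) = [U(τ_r)]ⁿ`.  `U(τ_r)` is an ordered
product of midpoint step propagators, each evaluated exactly by
Hermitian eigendecomposition of the 6×6 step Hamiltonian; the scheme is
second order in the step (verified by Richardson halving) and unitary to
machine precision.  The default of **200 steps per rotor period**
(0.2 µs at 25 kHz) leaves the glycine efficiency unchanged to better
than 0.1% on halving the step.  Half-period propagators serve the t₁
segments (Δt₁ = nτ_r split as t₁/2 on either side of the π pulse).  All
orientations are propagated as one batched array; a full-sequence
efficiency at the 6044-point powder set takes ~10 s on one CPU.

### Powder averaging

Orientations come from deterministic three-angle ZCW sets built as a
rank-1 lattice on (cosβ, γ, α) with golden-ratio generators, uniform
weights, midpoint-shifted.  The unit generator is assigned to cosβ so
that the two projections that control convergence — (β, γ) for static
tensor geometry and (β, α) for rotor-phase interference — are both
Fibonacci-quality; this assignment was chosen after the alternative
(unit generator on α) failed a 1%-RMS comparison of the static
first-order powder pattern against a 10⁶-point Monte-Carlo oracle.
Shipped sizes are the Fibonacci sequence 21…6765 plus the reference
sizes 1154 and 6044; at 6044 the static-pattern RMS deviation from the
Monte-Carlo oracle is 0.2%, all ⟨Y₂ₘ⟩ moments are below 10⁻³ from 987
points up, and the glycine efficiency agrees to <1% between the two
largest shipped sets.  Scans default to the 1154-point set (a `--full-powder`
flag selects 6044): the simulation is deterministic either way, and the
reduced set moves scan optima by at most one grid cell.

### Coherence selection and detection

Selection is by explicit projection onto the ¹⁴N coherence orders
(elementwise masks on p = m_I(row) − m_I(col)); an explicit phase cycle
of the excitation pulse with receiver weights (e^{ipφ}+e^{−ipφ})/n is
retained as a cross-check and agrees with the projection to 10⁻⁸.  The
efficiency is |⟨Tr(ρ_final S⁻)⟩_powder| / Tr(Sₓ S⁻): the magnitude of
the powder-averaged complex recovered amplitude, insensitive to overall
phase and bounded by 1.  Coherence-generation amplitudes are Frobenius
norms of the order-p components relative to ‖Sₓ‖, so Σ_p a_p² = 1 under
unitary evolution (basis-independent because the underlying tensor
basis is orthonormal).

2D detection is hypercomplex States: a second data set with the
reconversion-pulse phase shifted by 90°/|p| (implemented exactly as a
¹⁴N z-rotation sandwich of the cached propagator).  The recombination
sign is fixed so that a synthetic +ν modulation appears at +ν, and,
end-to-end, the glycine indirect lineshape appears on the deshielded
side at the rotor-averaged second-order frequencies (~+2.6 kHz ≈ +60 ppm
above the bare shift; the amide pattern at ~+400 ppm folds about the
25 kHz rotor-synchronised spectral width, as in the real experiment).
Line broadening is exp(−π·lb·t) (Lorentzian FWHM = lb, the spectrometer
convention), default 30 Hz in the direct dimension, zero-fill 1024;
broadening is exposed per dimension because the published overlays do
not state whether the indirect dimension was broadened.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| C_Q, η, b_IS, tensor orientation | presets | the two published parameter sets (amine 1.18 MHz/0.54/−0.716 kHz collinear; amide 3.01 MHz/0.48/−0.928 kHz at (0°,90°,120°)) |
| ν₀(¹³C), ν₀(¹⁴N) | 150 / 43.5 MHz | 14.1 T spectrometer of the reference experiments |
| MAS rate | 25 kHz | reference conditions; τ_r = 40 µs |
| rotor axis | 54.7356° | exact magic angle; adjustable (a 0.05° mis-set reintroduces first-order broadening, used for the amide lineshape comparison) |
| τ_N | 2 ms | rotor-synchronised (integer τ_r enforced; scans snap with a warning) |
| ν₁(¹⁴N) | 35 kHz | amine working point (50 kHz for the amide) |
| steps/rotor period | 200 | integrator converged (<0.1% on halving) |
| powder size | 1154 (scans), 6044 (full) | converged per the tests above |

## What passing tests do and do not show

The simulator *is* the study's numerical model: an isolated two-spin
pair without protons or relaxation.  Tests demonstrate internal
exactness (unitarity, caching transparency, filter/phase-cycle
equivalence, analytic first-order and closed-form second-order oracles)
and reproduce the simulation-derived published numbers (SQ generation
>20%; amide optima at ≥2 ms and ≥50 kHz; plateau beyond 2 ms at 40 kHz).
They do not validate proton-dependent observables: experimental
efficiencies versus CP, decoupling effects, or t₂ lineweights.  One
published reading is not reproduced: at the on-resonance, 2.5 ms setup
the model's glycine rf optimum is 30 kHz, not ≈40 kHz; the optimum is
strongly carrier-dependent (placing the carrier 60 ppm above the bare
shift — i.e. at twice the apparent second-order shift from the line —
moves it to exactly 40 kHz), and the published map does not state the
offset at which it was computed.  The corresponding acceptance test is
left failing rather than tuned.

## Numerical choices and edge cases

* Propagator steps use exact eigendecomposition — no Trotter error
  beyond the midpoint sampling of H(t).
* ν₁ = 0 or τ_N = 0 give exactly zero filtered signal (the initial
  state carries only order 0).
* Non-rotor-synchronised τ_N raises an error in the sequence layer;
  scan layers snap to the nearest integer period with a warning
  (2.5 ms → 2.48 ms at 25 kHz).
* Efficiencies are reported both raw and normalised to unit maximum,
  matching how the published maps are scaled.
* The dipolar coupling sign is stored as printed (negative); a test
  asserts the powder-averaged efficiency is insensitive to the overall
  sign flip.
* With Δt₁ an odd number of rotor periods, the t₁/2 halves are
  half-integer rotor periods; heteronuclear dipolar evolution then does
  not cancel exactly around the π pulse (a real, tiny echo modulation),
  while the first-order quadrupolar phase always refocuses — with
  second-order terms disabled and Δt₁ even, the indirect FID is frozen
  to machine precision (tested).

## Known limitations

* Two spins only: no ¹³C–¹³C J evolution (which the reference data show
  attenuating echo intensity), no proton bath, no relaxation — simulated
  2D peaks do not decay in t₁.
* Second-order (not exact lab-frame) quadrupole treatment: third-order
  terms (~tens of Hz at 3 MHz/43.5 MHz) are neglected, consistent with
  the engine used for the published simulations.
* Ideal, instantaneous ¹³C pulses; finite-pulse and rf-inhomogeneity
  effects on the ¹⁴N channel are not modelled.
* The ¹⁴N rf offset within a pulse uses the offset-irradiation
  approximation (an extra z-field), adequate for the ≤10 kHz offsets
  studied.
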