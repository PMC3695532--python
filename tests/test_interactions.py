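import numpy as np
import pytest
from scipy.linalg import expm

from quadspy.interactions import (
    MAGIC_ANGLE_DEG,
    DipolarInteraction,
    FieldSpec,
    HamiltonianGenerator,
    QuadrupoleInteraction,
    SpinSystemSpec,
    dipole_pas_components,
    hamiltonian_at,
    mas_fourier_coefficients,
    quad_pas_components,
    wigner_D2,
    wigner_d2,
    wigner_rotate,
)


def _system(cq=1.18, eta=0.54, dip=-0.716, euler=(0, 0, 0), **field_kw):
    return SpinSystemSpec(
        quadrupole=QuadrupoleInteraction(cq_mhz=cq, eta=eta, euler_to_dipole_deg=euler),
        dipole=DipolarInteraction(coupling_khz=dip),
        fields=FieldSpec(**field_kw),
    )


def _static_system(**kw):
    """Rotor axis along B0 and t = 0 turn the MAS chain into a static one."""
    return _system(rotor_axis_angle_deg=0.0, **kw)


# ----------------------------------------------------------------------
# Wigner rotations
# ----------------------------------------------------------------------

def test_reduced_wigner_against_matrix_exponential(rng):
    """Independent oracle: d²(β) = exp(−iβ J_y) built from scratch."""
    jp = np.zeros((5, 5), complex)
    for i, m in enumerate(range(-2, 2)):
        jp[i + 1, i] = np.sqrt(6 - m * (m + 1))
    jy = (jp - jp.conj().T) / 2j
    for beta in rng.uniform(0, np.pi, 10):
        assert np.allclose(wigner_d2(beta), expm(-1j * beta * jy).real, atol=1e-12)


def test_wigner_rotate_identity_and_norm(rng):
    A = rng.normal(size=5) + 1j * rng.normal(size=5)
    assert np.allclose(wigner_rotate(A, (0.0, 0.0, 0.0)), A)
    for _ in range(5):
        euler = rng.uniform(0, 2 * np.pi, 3)
        B = wigner_rotate(A, euler)
        assert np.isclose(np.sum(np.abs(B) ** 2), np.sum(np.abs(A) ** 2), rtol=1e-12)


def test_axial_tensor_at_90_degrees():
    """d²₀₀(90°) = −1/2: the secular part of an axial tensor flips sign/halves."""
    A = np.zeros(5, complex)
    A[2] = 1.0
    B = wigner_rotate(A, (0.0, np.pi / 2, 0.0))
    assert np.isclose(B[2].real, -0.5, atol=1e-12)


# ----------------------------------------------------------------------
# PAS components
# ----------------------------------------------------------------------

def test_quad_pas_components_structure():
    axial = quad_pas_components(QuadrupoleInteraction(cq_mhz=1.0, eta=0.0))
    assert np.allclose(axial[[0, 1, 3, 4]], 0.0)
    zero = quad_pas_components(QuadrupoleInteraction(cq_mhz=0.0, eta=0.7))
    assert np.allclose(zero, 0.0)
    gly = quad_pas_components(QuadrupoleInteraction(cq_mhz=1.18, eta=0.54))
    assert np.isclose(abs(gly[4] / gly[2]), 0.54 / np.sqrt(6), rtol=1e-12)
    assert np.allclose(dipole_pas_components(DipolarInteraction(0.0))[2], 0.0)


def test_eta_bounds_validated():
    with pytest.raises(ValueError):
        QuadrupoleInteraction(cq_mhz=1.0, eta=1.2)


# ----------------------------------------------------------------------
# first-order static spectrum: brute-force analytic oracle
# ----------------------------------------------------------------------

def test_static_first_order_frequencies_match_analytic(rng):
    """Hamiltonian eigenvalues reproduce the textbook spin-1 frequencies
    ±(3C_Q/8)(3cos²θ − 1 − η sin²θ cos2φ) on a grid of orientations."""
    cq, eta = 1.18, 0.54
    system = _static_system(cq=cq, eta=eta, dip=0.0)
    for _ in range(25):
        alpha = rng.uniform(0, 2 * np.pi)
        beta = np.arccos(rng.uniform(-1, 1))
        gamma = rng.uniform(0, 2 * np.pi)
        H = hamiltonian_at(0.0, system, (alpha, beta, gamma), include_second_order=False)
        d = np.diag(H).real / (2 * np.pi)
        nu_a, nu_b = d[0] - d[1], d[1] - d[2]  # the two SQ transitions
        analytic = (3 * cq * 1e6 / 8) * (
            3 * np.cos(beta) ** 2 - 1 - eta * np.sin(beta) ** 2 * np.cos(2 * gamma)
        )
        assert np.isclose(nu_a, analytic, rtol=0, atol=1e-3)
        assert np.isclose(nu_b, -analytic, rtol=0, atol=1e-3)


def test_hamiltonian_hermitian_and_rotor_periodic(glycine, rng):
    gen = HamiltonianGenerator(glycine, rng.uniform(0, np.pi, (4, 3)))
    tr = glycine.fields.rotor_period_s
    for t in (0.0, 0.3 * tr, 0.77 * tr):
        H = gen.hamiltonian(t)
        assert np.allclose(H, np.conj(np.swapaxes(H, -1, -2)), atol=1e-8)
        assert np.allclose(H, gen.hamiltonian(t + tr), atol=1e-6)


def test_zero_quadrupole_leaves_dipole_and_j():
    system = SpinSystemSpec(
        quadrupole=QuadrupoleInteraction(cq_mhz=0.0, eta=0.0),
        dipole=DipolarInteraction(coupling_khz=-0.716, j_hz=10.0),
        fields=FieldSpec(rotor_axis_angle_deg=0.0),
    )
    H = hamiltonian_at(0.0, system, (0.3, 0.9, 1.2))
    # all terms are ≤ dipole scale: no MHz-scale quadrupole left
    assert np.max(np.abs(H)) / (2 * np.pi) < 5e3


# ----------------------------------------------------------------------
# MAS Fourier structure
# ----------------------------------------------------------------------

def test_magic_angle_nulls_secular_average():
    A_rot = np.zeros(5, complex)
    A_rot[2] = 1.0
    c = mas_fourier_coefficients(A_rot, 25.0, MAGIC_ANGLE_DEG)
    assert abs(c[2]) < 1e-12  # c₀ = P₂(cos θ_m) = 0


def test_rotor_axis_misset_restores_secular_term():
    A_rot = np.zeros(5, complex)
    A_rot[2] = 1.0
    for misset in (0.05, -0.05, 0.2):
        theta = MAGIC_ANGLE_DEG + misset
        c = mas_fourier_coefficients(A_rot, 25.0, theta)
        p2 = 0.5 * (3 * np.cos(np.radians(theta)) ** 2 - 1)
        assert np.isclose(c[2].real, p2, atol=1e-12)


# ----------------------------------------------------------------------
# second-order terms
# ----------------------------------------------------------------------

def _second_order_diag(system, orientation, t=0.0):
    h2 = hamiltonian_at(t, system, orientation, include_second_order=True)
    h1 = hamiltonian_at(t, system, orientation, include_second_order=False)
    return np.diag(h2 - h1).real


def test_second_order_scales_inversely_with_larmor(rng):
    """Doubling the ¹⁴N Larmor frequency halves the quadrupolar
    second-order terms (pure self-terms: dipole set to zero)."""
    base = _static_system(dip=0.0)
    doubled = _static_system(dip=0.0, larmor_14n_mhz=87.0)
    for _ in range(5):
        ori = (rng.uniform(0, 2 * np.pi), np.arccos(rng.uniform(-1, 1)), rng.uniform(0, 2 * np.pi))
        d1 = _second_order_diag(base, ori)
        d2 = _second_order_diag(doubled, ori)
        assert np.allclose(d2, d1 / 2, rtol=1e-10, atol=1e-10)


def test_second_order_against_exact_diagonalization(rng):
    """Static oracle: perturbative SQ frequencies agree with brute-force
    diagonalization of Zeeman + full quadrupole to O(ω_Q³/ω₀²)."""
    cq, eta, nu0 = 1.18e6, 0.54, 43.5e6
    system = _static_system(cq=cq / 1e6, eta=eta, dip=0.0)
    # independent lab-frame matrices, built in the test
    m = np.array([1.0, 0.0, -1.0])
    Iz = np.diag(m)
    Ip = np.zeros((3, 3))
    Ip[0, 1] = Ip[1, 2] = np.sqrt(2)
    Im = Ip.T
    T2 = {
        0: (3 * Iz @ Iz - 2 * np.eye(3)) / np.sqrt(6),
        1: -(Iz @ Ip + Ip @ Iz) / 2,
        -1: (Iz @ Im + Im @ Iz) / 2,
        2: Ip @ Ip / 2,
        -2: Im @ Im / 2,
    }
    K = 2 * np.pi * cq / 4
    Apas = np.zeros(5, complex)
    Apas[2] = np.sqrt(6) * K
    Apas[0] = Apas[4] = -eta * K
    for _ in range(10):
        ori = (rng.uniform(0, 2 * np.pi), np.arccos(rng.uniform(-1, 1)), rng.uniform(0, 2 * np.pi))
        Alab = wigner_rotate(Apas, ori)
        V = sum((-1.0) ** mm * Alab[mm + 2] * T2[-mm] for mm in range(-2, 3))
        Hlab = -2 * np.pi * nu0 * Iz + V
        ev = np.sort(np.linalg.eigvalsh(Hlab))  # m=+1 lowest for −ω₀Iz
        # displayed SQ frequencies (offsets from the Larmor frequency)
        exact_a = -(ev[0] - ev[1]) / (2 * np.pi) - nu0
        exact_b = -(ev[1] - ev[2]) / (2 * np.pi) - nu0
        d = np.diag(hamiltonian_at(0.0, system, ori)).real / (2 * np.pi)
        pert_a, pert_b = -(d[0] - d[1]), -(d[1] - d[2])
        scale = (cq / 4) ** 2 / nu0  # second-order magnitude
        assert abs(pert_a - exact_a) < 0.05 * scale + 1.0
        assert abs(pert_b - exact_b) < 0.05 * scale + 1.0


def test_isotropic_second_order_shift_closed_form():
    """Orientation average of the SQ second-order shift equals
    +(3/40)(C_Q²/ν₀)(1 + η²/3) — derived by averaging the rank-2 and
    rank-4 parts away (they integrate to zero on the sphere)."""
    cq, eta, nu0 = 1.18e6, 0.54, 43.5e6
    system = _static_system(cq=cq / 1e6, eta=eta, dip=0.0)
    rng = np.random.default_rng(7)
    n = 4000
    alphas = rng.uniform(0, 2 * np.pi, n)
    betas = np.arccos(rng.uniform(-1, 1, n))
    gammas = rng.uniform(0, 2 * np.pi, n)
    gen2 = HamiltonianGenerator(system, np.column_stack([alphas, betas, gammas]))
    gen1 = HamiltonianGenerator(
        system, np.column_stack([alphas, betas, gammas]), include_second_order=False
    )
    d = (np.einsum("bii->bi", gen2.hamiltonian(0.0)) - np.einsum("bii->bi", gen1.hamiltonian(0.0))).real
    shift = -(d[:, 0] - d[:, 1]) / (2 * np.pi)  # displayed m=1↔0 transition
    closed_form = (3 / 40) * (cq**2 / nu0) * (1 + eta**2 / 3)
    assert np.isclose(shift.mean(), closed_form, rtol=0.05)
    assert shift.mean() > 0  # deshielded, as observed for spin-1 SQ lines


def test_euler_sense_flag():
    """The inverse Euler reading is a no-op for collinear tensors and a
    genuine physical alternative for the amide geometry."""
    from dataclasses import replace
    import quadspy as q

    exp = q.ExperimentSpec(tau_n_ms=0.8, nu1_n_khz=35.0)
    powder = q.zcw_set(55)
    gly = q.preset_system("glycine_amine")
    gly_inv = replace(gly, quadrupole=replace(gly.quadrupole, euler_sense="dipole_to_quad"))
    assert q.run_hnc_1d(gly, exp, powder).efficiency == q.run_hnc_1d(gly_inv, exp, powder).efficiency
    amide = q.preset_system("triglycine_amide")
    amide_inv = replace(amide, quadrupole=replace(amide.quadrupole, euler_sense="dipole_to_quad"))
    assert q.run_hnc_1d(amide, exp, powder).efficiency != q.run_hnc_1d(amide_inv, exp, powder).efficiency
    with pytest.raises(ValueError):
        QuadrupoleInteraction(1.0, 0.5, euler_sense="bogus")


def test_second_order_requires_larmor():
    bad = SpinSystemSpec(
        quadrupole=QuadrupoleInteraction(cq_mhz=1.0, eta=0.0),
        dipole=DipolarInteraction(coupling_khz=0.0),
        fields=FieldSpec(larmor_14n_mhz=-1.0),
    )
    with pytest.raises(ValueError):
        hamiltonian_at(0.0, bad, (0.0, 0.0, 0.0), include_second_order=True)
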