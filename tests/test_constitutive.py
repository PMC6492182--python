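"""Pointwise constitutive law: energies, analytic stresses, projections."""
import numpy as np
import pytest

from ventrimech.constitutive import (
    ActiveStressParams,
    CauchyStress,
    DeformationState,
    FiberFrame,
    InvalidDeformationError,
    MaterialDemiray,
    MaterialGuccione,
    active_stress_tensor,
    active_tension,
    passive_stress,
    project_stress,
    shell_volume_average,
    strain_energy,
    volume_average,
)

I3 = np.eye(3)


def random_deformation(rng, scale=0.15):
    """Random F with det F > 0, moderate strain."""
    while True:
        F = I3 + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.3:
            return DeformationState(F)


# ---------------------------------------------------------------------------
# strain energy
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mat", [MaterialDemiray(), MaterialGuccione()])
def test_energy_zero_at_reference(mat):
    assert strain_energy(DeformationState(I3), mat) == pytest.approx(0.0, abs=1e-14)


def test_energy_demiray_isochoric_uniaxial():
    # volume-preserving uniaxial stretch: closed-form scalar evaluation
    lam = 1.2
    F = np.diag([lam, lam ** -0.5, lam ** -0.5])
    trC = lam ** 2 + 2.0 / lam
    expected = 10.0 / 16.0 * (np.exp(8.0 * (trC - 3.0)) - 1.0)
    got = strain_energy(DeformationState(F), MaterialDemiray(a=10.0, b=8.0))
    assert got == pytest.approx(expected, rel=1e-12)


def test_energy_pure_dilatation_is_volumetric_only():
    # C_bar = I for F = gamma*I, so only the penalty term survives
    gamma = 1.07
    mat = MaterialDemiray()
    got = strain_energy(DeformationState(gamma * I3), mat)
    assert got == pytest.approx(0.5 * mat.kappa * (3.0 * np.log(gamma)) ** 2, rel=1e-12)


def test_energy_convex_along_dilatational_ray():
    mat = MaterialDemiray()
    gammas = np.linspace(0.8, 1.2, 41)
    psi = [strain_energy(DeformationState(g * I3), mat) for g in gammas]
    assert np.all(np.diff(psi, 2) > -1e-10)


def test_guccione_anisotropy_is_real():
    F = np.diag([1.15, 0.95, 0.93])
    frame = FiberFrame.cartesian()
    swapped = FiberFrame(frame.s0, -frame.f0, frame.n0)  # f<->s, right-handed
    mat = MaterialGuccione()
    psi_a = strain_energy(DeformationState(F, frame), mat)
    psi_b = strain_energy(DeformationState(F, swapped), mat)
    assert abs(psi_a - psi_b) > 1e-6
    iso = MaterialGuccione(b_f=3.58, b_t=3.58, b_fs=3.58)
    psi_c = strain_energy(DeformationState(F, frame), iso)
    psi_d = strain_energy(DeformationState(F, swapped), iso)
    assert psi_c == pytest.approx(psi_d, rel=1e-12)


def test_inadmissible_deformation_raises():
    with pytest.raises(InvalidDeformationError):
        DeformationState(np.diag([1.0, 1.0, -1.0]))


# ---------------------------------------------------------------------------
# passive stress vs finite-difference oracle
# ---------------------------------------------------------------------------

def _psi_of_C(C, mat, frame):
    """Independent scalar energy evaluated directly from C."""
    J = np.sqrt(np.linalg.det(C))
    Cbar = J ** (-2.0 / 3.0) * C
    vol = 0.5 * mat.kappa * np.log(J) ** 2
    if isinstance(mat, MaterialDemiray):
        return vol + mat.a / (2 * mat.b) * (np.exp(mat.b * (np.trace(Cbar) - 3)) - 1)
    R = frame.as_matrix()
    E = R.T @ (0.5 * (Cbar - I3)) @ R
    Q = (
        mat.b_f * E[0, 0] ** 2
        + mat.b_t * (E[1, 1] ** 2 + E[2, 2] ** 2 + 2 * E[1, 2] ** 2)
        + 2 * mat.b_fs * (E[0, 1] ** 2 + E[0, 2] ** 2)
    )
    return vol + 0.5 * mat.a * (np.exp(Q) - 1)


def _fd_stress(state, mat, h=1e-6):
    """sigma = J^-1 F (2 dPsi/dC) F^T with dPsi/dC by central differences."""
    C = state.C
    S = np.zeros((3, 3))
    for i in range(3):
        for j in range(i, 3):
            dC = np.zeros((3, 3))
            dC[i, j] = dC[j, i] = h
            dpsi = _psi_of_C(C + dC, mat, state.frame) - _psi_of_C(C - dC, mat, state.frame)
            S[i, j] = S[j, i] = dpsi / (2 * h) / (2.0 if i != j else 1.0)
    return state.F @ (2.0 * S) @ state.F.T / state.J


@pytest.mark.parametrize("mat", [MaterialDemiray(), MaterialGuccione()])
def test_passive_stress_matches_energy_derivative(mat, rng):
    for _ in range(100):
        state = random_deformation(rng)
        sig = passive_stress(state, mat).sigma
        oracle = _fd_stress(state, mat)
        scale = max(np.abs(oracle).max(), 1e-3)
        assert np.abs(sig - oracle).max() / scale < 1e-5


@pytest.mark.parametrize("mat", [MaterialDemiray(), MaterialGuccione()])
def test_passive_stress_reference_and_dilatation(mat):
    assert np.allclose(passive_stress(DeformationState(I3), mat).sigma, 0.0, atol=1e-14)
    gamma = 1.05
    sig = passive_stress(DeformationState(gamma * I3), mat).sigma
    J = gamma ** 3
    assert np.allclose(sig, mat.kappa * np.log(J) / J * I3, rtol=1e-10)


# ---------------------------------------------------------------------------
# active stress
# ---------------------------------------------------------------------------

def test_active_tension_transient_support_and_bounds():
    p = ActiveStressParams(S_peak=69.0, tau_c=80.0, tau_r=25.0, t_dur=300.0)
    assert active_tension(0.0, p) == 0.0
    assert active_tension(-5.0, p) == 0.0
    assert active_tension(300.0, p) == 0.0
    assert active_tension(400.0, p) == 0.0
    ts = np.linspace(1, 299, 120)
    vals = np.array([active_tension(t, p) for t in ts])
    assert np.all(vals >= 0) and np.all(vals <= p.S_peak)


def test_active_tension_midpoint_value():
    # direct scalar evaluation of the twitch formula
    p = ActiveStressParams(S_peak=69.0, tau_c=80.0, tau_r=25.0, t_dur=300.0)
    expected = 69.0 * np.tanh(150.0 / 80.0) ** 2 * np.tanh(150.0 / 25.0) ** 2
    assert active_tension(150.0, p) == pytest.approx(expected, rel=1e-12)


def test_active_stress_tensor_cases():
    state = DeformationState(I3)
    assert np.allclose(active_stress_tensor(state, 0.0).sigma, 0.0)
    sig = active_stress_tensor(state, 5.0).sigma
    f0 = state.frame.f0
    assert np.allclose(sig, 5.0 * np.outer(f0, f0), atol=1e-14)
    lam = 1.3
    state2 = DeformationState(np.diag([lam, 1.0, 1.0]))
    sig2 = active_stress_tensor(state2, 7.0).sigma
    expected = np.zeros((3, 3))
    expected[0, 0] = 7.0 / lam
    assert np.allclose(sig2, expected, rtol=1e-12)


# ---------------------------------------------------------------------------
# projection and averaging
# ---------------------------------------------------------------------------

def test_projection_isotropic_and_radial(rng):
    x, c = np.array([3.0, -2.0, 5.0]), np.zeros(3)
    iso = CauchyStress(4.2 * I3)
    assert np.allclose(project_stress(iso, x, c).sigma, 4.2 * I3, atol=1e-12)
    d = (x - c) / np.linalg.norm(x - c)
    rad = CauchyStress(3.3 * np.outer(d, d))
    proj = project_stress(rad, x, c).sigma
    assert proj[0, 0] == pytest.approx(3.3, rel=1e-12)
    off = proj.copy()
    off[0, 0] = 0.0
    assert np.abs(off).max() < 1e-12


def test_projection_preserves_invariants_and_roundtrip(rng):
    from ventrimech.constitutive import spherical_basis

    for _ in range(20):
        A = rng.standard_normal((3, 3))
        sig = CauchyStress(0.5 * (A + A.T))
        x = rng.standard_normal(3) * 10
        proj = project_stress(sig, x, np.zeros(3))
        assert np.trace(proj.sigma) == pytest.approx(np.trace(sig.sigma), rel=1e-10, abs=1e-12)
        assert np.allclose(
            np.sort(np.linalg.eigvalsh(proj.sigma)),
            np.sort(np.linalg.eigvalsh(sig.sigma)),
            atol=1e-10,
        )
        P = spherical_basis(x, np.zeros(3))
        back = P @ proj.sigma @ P.T
        assert np.abs(back - sig.sigma).max() < 1e-12 * max(1, np.abs(sig.sigma).max())


def test_projection_undefined_at_center():
    with pytest.raises(ValueError):
        project_stress(CauchyStress(I3), np.zeros(3), np.zeros(3))


def test_volume_average_properties(rng):
    w = rng.random(50) + 0.1
    assert volume_average(np.full(50, 3.7), w) == pytest.approx(3.7)
    a, b = rng.standard_normal(50), rng.standard_normal(50)
    assert volume_average(a + b, w) == pytest.approx(
        volume_average(a, w) + volume_average(b, w)
    )
    vals = rng.standard_normal(50)
    m = volume_average(vals, w)
    assert vals.min() <= m <= vals.max()


def test_shell_average_linear_profile_closed_form():
    rho = np.linspace(1.0, 2.0, 20001)
    # int rho * rho^2 / int rho^2 on [1,2] = (15/4)/(7/3) = 45/28
    assert shell_volume_average(rho, rho) == pytest.approx(45.0 / 28.0, rel=1e-8)
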