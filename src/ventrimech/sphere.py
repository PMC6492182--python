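"""Ground-truth inflation of a thick-walled hyperelastic spherical shell.

Two semi-analytic solvers are provided for the pressurized isotropic
(Demiray) shell with inner/outer reference radii ``r0 < R0``:

1. an *exactly incompressible* radial reduction: each material sphere at
   reference radius ``xi`` moves to ``rho = (xi^3 + r^3 - r0^3)^(1/3)``,
   with hoop stretch ``lam = rho/xi`` and radial stretch ``lam^-2``; the
   luminal pressure follows from the radial equilibrium quadrature
   ``p = int_r^R 2 (sigma_theta - sigma_rr) / rho  drho``;

2. a *nearly incompressible* radial boundary-value problem in which the
   volumetric response is the penalty ``kappa * ln(J)/J`` of the material
   law itself, solved by shooting on the deformed inner radius.  This is
   the formulation used by the finite-element reference this package
   mirrors, and at hoop stresses of order 100 kPa the two differ visibly
   (ln J ~ sigma/kappa), so the penalty solver is the one used for the
   verification tables.

An optional isotropic in-plane active tension ``S_a`` (added equally to
both hoop stresses) turns the passive shell into the lumped contracting
ventricle used by :mod:`ventrimech.cycle`.

Units: kPa, mm, ms, ml.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_simpson, solve_ivp
from scipy.optimize import brentq

from .constitutive import MaterialDemiray, shell_volume_average
from .units import J_PER_KPA_ML, MM3_PER_ML

__all__ = [
    "SphereGeometry",
    "InflationState",
    "PVCurve",
    "pressure_from_inner_radius",
    "inflate",
    "mean_stresses",
    "edpvr",
    "internal_work",
    "external_work",
    "inflate_penalty",
    "SPHERE_BENCHMARKS",
]


class SolverError(RuntimeError):
    """Root-finding or BVP integration failed to converge."""


@dataclass(frozen=True)
class SphereGeometry:
    """Reference (unloaded) shell geometry in mm."""

    r0: float
    R0: float

    def __post_init__(self) -> None:
        if not 0 < self.r0 < self.R0:
            raise ValueError("need 0 < r0 < R0")

    @property
    def h0(self) -> float:
        return self.R0 - self.r0

    @property
    def cavity_volume0(self) -> float:
        """Reference cavity volume in ml."""
        return 4.0 / 3.0 * np.pi * self.r0 ** 3 / MM3_PER_ML

    @property
    def wall_volume(self) -> float:
        """Wall volume in ml (conserved exactly by the incompressible map)."""
        return 4.0 / 3.0 * np.pi * (self.R0 ** 3 - self.r0 ** 3) / MM3_PER_ML

    def outer_from_inner(self, r: float) -> float:
        """Deformed outer radius for deformed inner radius r (J = 1)."""
        return float(np.cbrt(self.R0 ** 3 - self.r0 ** 3 + r ** 3))


#: Table of verification shell geometries (thin / intermediate / LV-like).
SPHERE_BENCHMARKS = {
    "Sph_5": SphereGeometry(15.0, 15.5),
    "Sph_25": SphereGeometry(15.0, 17.5),
    "Sph_150": SphereGeometry(15.0, 30.0),
}


@dataclass(frozen=True)
class InflationState:
    """Converged inflation state with sampled radial stress profiles.

    ``rho`` are deformed radial sample positions spanning [r, R]; the
    profiles are total Cauchy stresses (kPa) including any active tension.
    """

    geom: SphereGeometry
    p: float
    r: float
    R: float
    rho: np.ndarray
    sigma_rr: np.ndarray
    sigma_theta: np.ndarray
    sigma_phi: np.ndarray
    S_a: float = 0.0

    @property
    def cavity_volume(self) -> float:
        """Deformed cavity volume in ml."""
        return 4.0 / 3.0 * np.pi * self.r ** 3 / MM3_PER_ML

    @property
    def wall_volume(self) -> float:
        """Deformed wall volume in ml."""
        return 4.0 / 3.0 * np.pi * (self.R ** 3 - self.r ** 3) / MM3_PER_ML

    @property
    def h(self) -> float:
        return self.R - self.r


@dataclass(frozen=True)
class PVCurve:
    """Passive pressure-volume relation (kPa vs ml)."""

    pressures: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, float)
        if np.any(np.diff(v) <= 0):
            raise ValueError("passive inflation must have strictly increasing volume")


# ---------------------------------------------------------------------------
# incompressible radial reduction
# ---------------------------------------------------------------------------

def _dev_response(mat: MaterialDemiray, lam: np.ndarray) -> np.ndarray:
    """sigma_theta - sigma_rr for the incompressible Demiray shell.

    With hoop stretch lam and radial stretch lam^-2,
    I1 = 2 lam^2 + lam^-4 and the stress difference is
    a * exp(b (I1 - 3)) * (lam^2 - lam^-4).
    """
    I1 = 2.0 * lam ** 2 + lam ** -4
    return mat.a * np.exp(mat.b * (I1 - 3.0)) * (lam ** 2 - lam ** -4)


def _gauss_nodes(a: float, b: float, n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (b - a) * x + 0.5 * (a + b), 0.5 * (b - a) * w


def pressure_from_inner_radius(
    geom: SphereGeometry,
    mat: MaterialDemiray,
    r_def: float,
    S_a: float = 0.0,
    n_quad: int = 200,
) -> float:
    """Luminal pressure (kPa) balancing the shell at deformed inner radius.

    Gauss-Legendre quadrature of the radial equilibrium integral on the
    reference thickness coordinate; exact for the incompressible kinematics.
    Monotone increasing in both ``r_def`` and ``S_a``.  Negative values are
    returned for ``r_def < r0`` (compressed shell).
    """
    if r_def <= 0:
        raise ValueError("deformed inner radius must be positive")
    xi, w = _gauss_nodes(geom.r0, geom.R0, n_quad)
    d = r_def ** 3 - geom.r0 ** 3
    rho = np.cbrt(xi ** 3 + d)
    lam = rho / xi
    integrand = 2.0 * (_dev_response(mat, lam) + S_a) / rho * xi ** 2 / rho ** 2
    return float(np.sum(w * integrand))


def inflate(
    geom: SphereGeometry,
    mat: MaterialDemiray,
    p_target: float,
    S_a: float = 0.0,
    n_profile: int = 1001,
    n_quad: int = 200,
) -> InflationState:
    """Solve the incompressible shell for a target luminal pressure.

    Bracketed root-find on the deformed inner radius; the returned state
    satisfies ``|p - p_target| < 1e-8`` kPa and carries radial stress
    profiles sampled at ``n_profile`` points.
    """
    if p_target < 0:
        raise ValueError("p_target must be nonnegative")

    def f(r):
        return pressure_from_inner_radius(geom, mat, r, S_a=S_a, n_quad=n_quad) - p_target

    lo = geom.r0 * (0.2 if S_a > 0 else 1.0)
    hi = geom.r0
    if f(hi) >= 0.0 and S_a == 0.0 and p_target == 0.0:
        r = geom.r0
    else:
        while f(hi) < 0.0:
            hi *= 1.25
            if hi > 50 * geom.r0:
                raise SolverError("inflation bracket expansion failed")
        try:
            r = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
        except ValueError as exc:  # pragma: no cover - defensive
            raise SolverError(f"inflation root-find failed: {exc}") from exc
    return _state_from_inner_radius(geom, mat, r, S_a, n_profile)


def _state_from_inner_radius(
    geom: SphereGeometry,
    mat: MaterialDemiray,
    r: float,
    S_a: float,
    n_profile: int = 1001,
) -> InflationState:
    """Build stress profiles for a known deformed inner radius (J = 1)."""
    xi = np.linspace(geom.r0, geom.R0, n_profile)
    rho = np.cbrt(xi ** 3 + (r ** 3 - geom.r0 ** 3))
    lam = rho / xi
    dev = _dev_response(mat, lam) + S_a
    # sigma_rr(rho) = sigma_rr(R) - int_rho^R 2 dev / rho' drho', sigma_rr(R) = 0
    cum = cumulative_simpson(2.0 * dev / rho, x=rho, initial=0.0)
    p = cum[-1]
    sigma_rr = cum - p
    sigma_theta = sigma_rr + dev
    return InflationState(
        geom=geom,
        p=float(p),
        r=float(rho[0]),
        R=float(rho[-1]),
        rho=rho,
        sigma_rr=sigma_rr,
        sigma_theta=sigma_theta,
        sigma_phi=sigma_theta.copy(),
        S_a=S_a,
    )


def mean_stresses(state: InflationState):
    """Volume-averaged (sigma_rr, sigma_theta, sigma_phi) in kPa.

    Averages are taken over the deformed shell; by radial symmetry the
    meridional and azimuthal means coincide exactly.
    """
    m_rr = shell_volume_average(state.sigma_rr, state.rho)
    m_tt = shell_volume_average(state.sigma_theta, state.rho)
    m_pp = shell_volume_average(state.sigma_phi, state.rho)
    return m_rr, m_tt, m_pp


def edpvr(
    geom: SphereGeometry,
    mat: MaterialDemiray,
    pressures: Sequence[float],
    n_profile: int = 401,
) -> PVCurve:
    """Passive pressure-volume curve over a nonnegative pressure grid."""
    pressures = np.asarray(pressures, float)
    if np.any(pressures < 0) or np.any(np.diff(pressures) <= 0):
        raise ValueError("pressure grid must be nonnegative and increasing")
    vols = [
        inflate(geom, mat, p, n_profile=n_profile).cavity_volume for p in pressures
    ]
    return PVCurve(pressures=pressures, volumes=np.asarray(vols))


# ---------------------------------------------------------------------------
# work integrals
# ---------------------------------------------------------------------------

def internal_work(states: Sequence[InflationState]) -> float:
    """Internal mechanical work (J) along an ordered quasi-static ramp.

    Integrates the stress power density ``sigma : deps`` over the shell and
    the ramp.  For the radially symmetric incompressible motion the strain
    increments at a material point are ``deps_theta = drho/rho`` and
    ``deps_rr = -2 drho/rho``, and the deformed volume element equals the
    reference one, so the work reduces to a double trapezoid over the
    reference thickness coordinate and the ramp steps.
    """
    if len(states) < 2:
        return 0.0
    ps = [s.p for s in states]
    if any(b < a for a, b in zip(ps, ps[1:])):
        raise ValueError("ramp states must be ordered by nondecreasing pressure")
    geom = states[0].geom
    n = len(states[0].rho)
    xi = np.linspace(geom.r0, geom.R0, n)
    W = 0.0
    for s0, s1 in zip(states[:-1], states[1:]):
        rho0, rho1 = s0.rho, s1.rho
        rho_m = 0.5 * (rho0 + rho1)
        drho = rho1 - rho0
        # sigma : deps = (sig_t + sig_p - 2 sig_r) * drho / rho at midpoint
        sig_t = 0.5 * (s0.sigma_theta + s1.sigma_theta)
        sig_p = 0.5 * (s0.sigma_phi + s1.sigma_phi)
        sig_r = 0.5 * (s0.sigma_rr + s1.sigma_rr)
        dens = (sig_t + sig_p - 2.0 * sig_r) * drho / rho_m
        W += np.trapezoid(dens * 4.0 * np.pi * xi ** 2, xi)
    return float(W * 1e-6)  # kPa mm^3 -> J


def external_work(p: Sequence[float], V_cav: Sequence[float]) -> float:
    """PV work (J): trapezoid integral of p dV, positive for inflation."""
    p = np.asarray(p, float)
    V = np.asarray(V_cav, float)
    if p.shape != V.shape:
        raise ValueError("pressure and volume traces must have equal length")
    return float(np.trapezoid(p, V) * J_PER_KPA_ML)


# ---------------------------------------------------------------------------
# nearly incompressible (penalty) radial BVP
# ---------------------------------------------------------------------------

def _principal_stresses(mat: MaterialDemiray, lam_r, lam_t):
    """Cauchy (sigma_rr, sigma_theta) for the compressible Demiray law."""
    J = lam_r * lam_t ** 2
    I1 = lam_r ** 2 + 2.0 * lam_t ** 2
    I1b = J ** (-2.0 / 3.0) * I1
    E = mat.a * np.exp(mat.b * (I1b - 3.0)) / J
    vol = mat.kappa * np.log(J) / J
    s_r = vol + E * (J ** (-2.0 / 3.0) * lam_r ** 2 - I1b / 3.0)
    s_t = vol + E * (J ** (-2.0 / 3.0) * lam_t ** 2 - I1b / 3.0)
    return s_r, s_t


def _penalty_rhs(mat: MaterialDemiray):
    h = 1e-7

    def rhs(xi, y):
        rho, lam_r = y
        lam_t = rho / xi
        s_r, s_t = _principal_stresses(mat, lam_r, lam_t)
        dsr_dlr = (
            _principal_stresses(mat, lam_r + h, lam_t)[0]
            - _principal_stresses(mat, lam_r - h, lam_t)[0]
        ) / (2 * h)
        dsr_dlt = (
            _principal_stresses(mat, lam_r, lam_t + h)[0]
            - _principal_stresses(mat, lam_r, lam_t - h)[0]
        ) / (2 * h)
        dlam_t = lam_r / xi - rho / xi ** 2
        dlam_r = (2.0 * (s_t - s_r) / rho * lam_r - dsr_dlt * dlam_t) / dsr_dlr
        return [lam_r, dlam_r]

    return rhs


def _penalty_shoot(geom: SphereGeometry, mat: MaterialDemiray, r_inner: float, p: float):
    lam_t0 = r_inner / geom.r0

    def inner_bc(lr):
        return _principal_stresses(mat, lr, lam_t0)[0] + p

    lam_r0 = brentq(inner_bc, 0.02, 5.0, xtol=1e-14)
    sol = solve_ivp(
        _penalty_rhs(mat),
        (geom.r0, geom.R0),
        [r_inner, lam_r0],
        rtol=1e-10,
        atol=1e-12,
        dense_output=True,
    )
    if not sol.success:  # pragma: no cover - defensive
        raise SolverError(f"penalty BVP integration failed: {sol.message}")
    rho_out, lr_out = sol.y[:, -1]
    s_r_out, _ = _principal_stresses(mat, lr_out, rho_out / geom.R0)
    return s_r_out, sol


def inflate_penalty(
    geom: SphereGeometry,
    mat: MaterialDemiray,
    p_target: float,
    n_profile: int = 1001,
) -> InflationState:
    """Nearly incompressible inflation (penalty bulk term, shooting BVP).

    Matches the volumetric treatment of the finite-element reference:
    J deviates from 1 by O(sigma/kappa), which matters for thin shells at
    high hoop stress.  Returns the same :class:`InflationState` container;
    note the incompressibility identity holds only approximately here.
    """
    if p_target < 0:
        raise ValueError("p_target must be nonnegative")
    if p_target == 0:
        return _state_from_inner_radius(geom, mat, geom.r0, 0.0, n_profile)

    def resid(ri):
        return _penalty_shoot(geom, mat, ri, p_target)[0]

    lo, hi = geom.r0 * (1 + 1e-9), geom.r0 * 1.05
    while resid(hi) < 0:
        hi *= 1.15
        if hi > 5 * geom.r0:  # pragma: no cover - defensive
            raise SolverError("penalty shooting bracket expansion failed")
    r = brentq(resid, lo, hi, xtol=1e-11)
    _, sol = _penalty_shoot(geom, mat, r, p_target)
    xi = np.linspace(geom.r0, geom.R0, n_profile)
    rho, lam_r = sol.sol(xi)
    s_r, s_t = _principal_stresses(mat, lam_r, rho / xi)
    return InflationState(
        geom=geom,
        p=float(p_target),
        r=float(rho[0]),
        R=float(rho[-1]),
        rho=rho,
        sigma_rr=s_r,
        sigma_theta=s_t,
        sigma_phi=s_t.copy(),
    )
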