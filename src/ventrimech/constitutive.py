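"""Hyperelastic constitutive laws for passive and active myocardium.

Two strain-energy functions are provided, both split into a volumetric
penalty term ``kappa/2 * (ln J)^2`` and an isochoric part evaluated on the
modified (volume-preserving) deformation:

* the isotropic exponential (Demiray) model,
  ``Psi_iso = a/(2b) * (exp(b*(tr(Cbar) - 3)) - 1)``, and
* the transversely isotropic Guccione model,
  ``Psi_iso = a/2 * (exp(Q) - 1)`` with a quadratic form ``Q`` in the
  components of the modified Green-Lagrange strain expressed in the local
  fiber-sheet-normal frame.

Cauchy stresses are obtained analytically from
``sigma_pas = J^-1 F (2 dPsi/dC) F^T``; the test suite checks the analytic
derivative against central finite differences of the scalar energy.

Active contraction follows a phenomenological twitch: a scalar tension
transient ``S_a(t)`` (tanh^2 upstroke / downstroke) acting along the
deformed fiber direction,
``sigma_act = J^-1 S_a (f0.C f0)^-1 (F f0) ox (F f0)``.

Units: stresses in kPa, times in ms, lengths dimensionless (stretches).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

__all__ = [
    "MaterialDemiray",
    "MaterialGuccione",
    "FiberFrame",
    "DeformationState",
    "ActiveStressParams",
    "CauchyStress",
    "strain_energy",
    "passive_stress",
    "active_tension",
    "active_stress_tensor",
    "project_stress",
    "spherical_basis",
    "volume_average",
    "shell_volume_average",
]

_I3 = np.eye(3)


class InvalidDeformationError(ValueError):
    """Raised when a deformation gradient is not admissible (det F <= 0)."""


@dataclass(frozen=True)
class MaterialDemiray:
    """Isotropic exponential material.

    Parameters
    ----------
    a : stress scale (kPa), > 0
    b : dimensionless exponent, > 0
    kappa : bulk modulus / incompressibility penalty (kPa), > 0
    """

    a: float = 10.0
    b: float = 8.0
    kappa: float = 650.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.kappa > 0):
            raise ValueError("Demiray parameters a, b, kappa must be positive")


@dataclass(frozen=True)
class MaterialGuccione:
    """Transversely isotropic Guccione-type material (kPa / dimensionless)."""

    a: float = 0.5
    b_f: float = 18.48
    b_t: float = 3.58
    b_fs: float = 1.627
    kappa: float = 650.0

    def __post_init__(self) -> None:
        if min(self.a, self.b_f, self.b_t, self.b_fs, self.kappa) <= 0:
            raise ValueError("Guccione parameters must be positive")


Material = Union[MaterialDemiray, MaterialGuccione]


@dataclass(frozen=True)
class FiberFrame:
    """Right-handed orthonormal fiber / sheet / sheet-normal triad."""

    f0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray

    def __post_init__(self) -> None:
        R = self.as_matrix()
        if not np.allclose(R.T @ R, _I3, atol=1e-9):
            raise ValueError("fiber frame vectors must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("fiber frame must be right-handed (det = +1)")

    def as_matrix(self) -> np.ndarray:
        """Columns are (f0, s0, n0)."""
        return np.column_stack([self.f0, self.s0, self.n0])

    @staticmethod
    def cartesian() -> "FiberFrame":
        return FiberFrame(_I3[:, 0].copy(), _I3[:, 1].copy(), _I3[:, 2].copy())


@dataclass(frozen=True)
class DeformationState:
    """Deformation gradient plus the local reference fiber frame."""

    F: np.ndarray
    frame: FiberFrame = field(default_factory=FiberFrame.cartesian)

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "F", F)
        if F.shape != (3, 3):
            raise ValueError("F must be a 3x3 matrix")
        if np.linalg.det(F) <= 0:
            raise InvalidDeformationError("det F must be positive")

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F


@dataclass(frozen=True)
class ActiveStressParams:
    """Phenomenological twitch parameters.

    S_peak : peak isometric tension (kPa)
    tau_c  : upstroke time constant (ms)
    tau_r  : downstroke time constant (ms)
    t_dur  : transient duration (ms)
    length_dependence : phi(lambda); defaults to the constant 1
    """

    S_peak: float = 69.0
    tau_c: float = 80.0
    tau_r: float = 30.0
    t_dur: float = 300.0
    length_dependence: Callable[[float], float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.S_peak < 0:
            raise ValueError("S_peak must be nonnegative")
        if min(self.tau_c, self.tau_r, self.t_dur) <= 0:
            raise ValueError("time constants must be positive")
        if self.length_dependence is None:
            object.__setattr__(self, "length_dependence", lambda lam: 1.0)


@dataclass(frozen=True)
class CauchyStress:
    """Symmetric Cauchy stress tensor (kPa) with a basis tag."""

    sigma: np.ndarray
    basis: str = "cartesian"

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "sigma", s)
        if s.shape != (3, 3):
            raise ValueError("sigma must be 3x3")
        if not np.allclose(s, s.T, atol=1e-8 * max(1.0, np.abs(s).max())):
            raise ValueError("Cauchy stress must be symmetric")


# ---------------------------------------------------------------------------
# strain energy
# ---------------------------------------------------------------------------

def _check_C(C: np.ndarray) -> None:
    if np.any(np.linalg.eigvalsh(C) <= 0):
        raise InvalidDeformationError("right Cauchy-Green tensor not positive definite")


def _guccione_Q_and_D(mat: MaterialGuccione, Ebar_frame: np.ndarray):
    """Quadratic exponent Q and its derivative dQ/dEbar in frame coordinates."""
    E = Ebar_frame
    # weight matrix, elementwise on the symmetric strain components
    M = np.array(
        [
            [mat.b_f, mat.b_fs, mat.b_fs],
            [mat.b_fs, mat.b_t, mat.b_t],
            [mat.b_fs, mat.b_t, mat.b_t],
        ]
    )
    Q = (
        mat.b_f * E[0, 0] ** 2
        + mat.b_t * (E[1, 1] ** 2 + E[2, 2] ** 2 + 2 * E[1, 2] ** 2)
        + 2 * mat.b_fs * (E[0, 1] ** 2 + E[0, 2] ** 2)
    )
    dQ_dE = 2.0 * M * E
    return Q, dQ_dE


def strain_energy(state: DeformationState, mat: Material) -> float:
    """Strain-energy density Psi (kPa) at a material point.

    Zero in the reference configuration and nonnegative in a neighbourhood
    of it; raises :class:`InvalidDeformationError` for inadmissible F.
    """
    F = state.F
    J = state.J
    C = F.T @ F
    _check_C(C)
    Cbar = J ** (-2.0 / 3.0) * C
    vol = 0.5 * mat.kappa * np.log(J) ** 2
    if isinstance(mat, MaterialDemiray):
        iso = mat.a / (2.0 * mat.b) * (np.exp(mat.b * (np.trace(Cbar) - 3.0)) - 1.0)
    else:
        R = state.frame.as_matrix()
        Ebar = 0.5 * (Cbar - _I3)
        Q, _ = _guccione_Q_and_D(mat, R.T @ Ebar @ R)
        iso = 0.5 * mat.a * (np.exp(Q) - 1.0)
    return float(vol + iso)


# ---------------------------------------------------------------------------
# passive Cauchy stress (analytic dPsi/dC)
# ---------------------------------------------------------------------------

def passive_stress(state: DeformationState, mat: Material) -> CauchyStress:
    """Passive Cauchy stress ``J^-1 F (2 dPsi/dC) F^T`` (kPa), analytic."""
    F = state.F
    J = state.J
    C = F.T @ F
    _check_C(C)
    B = F @ F.T
    Jm23 = J ** (-2.0 / 3.0)
    vol = mat.kappa * np.log(J) / J * _I3
    if isinstance(mat, MaterialDemiray):
        Cbar_tr = Jm23 * np.trace(C)
        coef = mat.a * np.exp(mat.b * (Cbar_tr - 3.0))
        # deviatoric push-forward of the isochoric stress
        iso = coef * Jm23 / J * (B - np.trace(B) / 3.0 * _I3)
    else:
        R = state.frame.as_matrix()
        Ebar = 0.5 * (Jm23 * C - _I3)
        Q, dQ_frame = _guccione_Q_and_D(mat, R.T @ Ebar @ R)
        D = R @ dQ_frame @ R.T  # dQ/dEbar in cartesian coordinates
        coef = 0.5 * mat.a * np.exp(Q) * 0.5  # a/2 e^Q * (dEbar/dCbar = 1/2)
        FDFt = F @ D @ F.T
        iso = 2.0 * coef * Jm23 / J * (FDFt - np.trace(D @ C) / 3.0 * _I3)
    sig = vol + iso
    return CauchyStress(0.5 * (sig + sig.T))


# ---------------------------------------------------------------------------
# active stress
# ---------------------------------------------------------------------------

def active_tension(t_s: float, p: ActiveStressParams, lam: float = 1.0) -> float:
    """Scalar active fiber tension S_a(t_s) in kPa.

    ``t_s`` is the time elapsed since local activation onset; the transient
    has support (0, t_dur) and is clamped to zero outside it.
    """
    if t_s <= 0.0 or t_s >= p.t_dur:
        return 0.0
    up = np.tanh(t_s / p.tau_c) ** 2
    down = np.tanh((p.t_dur - t_s) / p.tau_r) ** 2
    return float(p.S_peak * p.length_dependence(lam) * up * down)


def active_tension_trace(t_s: np.ndarray, p: ActiveStressParams, lam: float = 1.0) -> np.ndarray:
    """Vectorized :func:`active_tension` over an array of times."""
    t_s = np.asarray(t_s, dtype=float)
    inside = (t_s > 0.0) & (t_s < p.t_dur)
    out = np.zeros_like(t_s)
    ts = t_s[inside]
    out[inside] = (
        p.S_peak
        * p.length_dependence(lam)
        * np.tanh(ts / p.tau_c) ** 2
        * np.tanh((p.t_dur - ts) / p.tau_r) ** 2
    )
    return out


def active_stress_tensor(state: DeformationState, S_a: float) -> CauchyStress:
    """Rank-1 active Cauchy stress along the deformed fiber direction."""
    if S_a < 0:
        raise ValueError("S_a must be nonnegative")
    F = state.F
    f0 = state.frame.f0
    Ff0 = F @ f0
    fCf = float(f0 @ (F.T @ F) @ f0)
    sig = S_a / state.J / fCf * np.outer(Ff0, Ff0)
    return CauchyStress(sig)


# ---------------------------------------------------------------------------
# basis projection and averaging
# ---------------------------------------------------------------------------

def spherical_basis(x: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Projection matrix P = (e_r, e_phi, e_theta) at position x.

    e_r is radial, e_phi azimuthal and e_theta meridional for a spherical
    coordinate system centred at ``center``.
    """
    d = np.asarray(x, float) - np.asarray(center, float)
    rn = np.linalg.norm(d)
    if rn == 0.0:
        raise ValueError("spherical basis undefined at the center")
    e_r = d / rn
    # meridional/azimuthal directions from the polar axis e_z
    ez = np.array([0.0, 0.0, 1.0])
    horiz = ez - (ez @ e_r) * e_r
    hn = np.linalg.norm(horiz)
    if hn < 1e-12:  # on the polar axis: any tangential pair works
        e_theta = np.array([1.0, 0.0, 0.0])
    else:
        e_theta = -horiz / hn
    e_phi = np.cross(e_theta, e_r)
    return np.column_stack([e_r, e_phi, e_theta])


def project_stress(sig: CauchyStress, x: np.ndarray, center: np.ndarray) -> CauchyStress:
    """Recast a Cartesian Cauchy stress into the spherical basis at x.

    Orthogonal change of basis ``sigma_sph = P^T sigma P``; eigenvalues and
    trace are preserved exactly.
    """
    P = spherical_basis(x, center)
    return CauchyStress(P.T @ sig.sigma @ P, basis="spherical")


def volume_average(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted mean of a sampled field, weights being volume elements."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    W = weights.sum()
    if W <= 0:
        raise ValueError("zero-volume averaging domain")
    return float((values * weights).sum() / W)


def shell_volume_average(g: np.ndarray, rho: np.ndarray) -> float:
    """Volume average of a radial profile g(rho) over a spherical shell.

    Reduces the volume integral to ``int g * 4 pi rho^2 drho / V_shell``
    by radial symmetry (trapezoid rule on the sampled profile).
    """
    rho = np.asarray(rho, float)
    g = np.asarray(g, float)
    w = rho ** 2
    denom = np.trapezoid(w, rho)
    if denom <= 0:
        raise ValueError("zero-volume shell")
    return float(np.trapezoid(g * w, rho) / denom)
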