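"""Laplace-law estimators of ventricular wall stress, power and efficiency.

Three clinically used hoop-stress estimates for a pressurized ventricle
approximated as a spherical shell (pressure p in kPa, radii in mm,
volumes in ml):

* thin-wall    ``sigma_L,h = p r / (2 h)``
* thick-wall   ``sigma_L,H = p r / (2 h) / (1 + h / (2 r))``
* volume-based ``sigma_L,V = p / (((V_cav + V_myo) / V_cav)^(2/3) - 1)``

``sigma_L,V`` is algebraically identical to ``sigma_L,H`` on an exact
sphere and differs only for nonspherical geometry.  From these, the
module derives the Laplace power estimate
``P_int,* = V_myo sigma_L,* (rdot/r0 + Rdot/R0)`` (the bracket
approximating the in-plane strain rate), cumulative work, the relative
internal heart work/power indicators (IHW, IHP), hydrodynamic power
``p q``, the external heart power EHP (systolic time average of
``p_ao q``, approximately MAP x CO), and the two power-efficiency ratios.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .units import J_PER_KPA_ML

__all__ = [
    "sigma_thin",
    "sigma_thick",
    "sigma_volume",
    "finite_difference_rate",
    "laplace_power",
    "work_from_power",
    "ihw_ihp",
    "hydrodynamic_power",
    "ehp",
    "power_efficiency",
    "mean_arterial_pressure",
    "LaplaceSeries",
    "PowerSummary",
]


def _require_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")


def sigma_thin(p, r, h):
    """Thin-wall Laplace hoop stress p*r/(2h) in kPa (scale invariant)."""
    r = np.asarray(r, float)
    h = np.asarray(h, float)
    if np.any(r <= 0) or np.any(h <= 0):
        raise ValueError("radius and wall width must be positive")
    return p * r / (2.0 * h)


def sigma_thick(p, r, h):
    """Thick-wall Laplace hoop stress, the thin-wall value over 1 + h/(2r).

    Equals ``p r^2 / ((r+h)^2 - r^2)``; strictly below the thin-wall
    estimate for any h > 0 and converging to it as h/r -> 0.
    """
    r = np.asarray(r, float)
    h = np.asarray(h, float)
    if np.any(r <= 0) or np.any(h <= 0):
        raise ValueError("radius and wall width must be positive")
    return p * r / (2.0 * h) / (1.0 + h / (2.0 * r))


def sigma_volume(p, V_cav, V_myo):
    """Volume-based Laplace hoop stress in kPa.

    ``p / (((V_cav + V_myo)/V_cav)^(2/3) - 1)``; coincides with
    :func:`sigma_thick` when the volumes come from a concentric sphere.
    """
    V_cav = np.asarray(V_cav, float)
    V_myo = np.asarray(V_myo, float)
    if np.any(V_cav <= 0) or np.any(V_myo <= 0):
        raise ValueError("volumes must be positive")
    return p / (((V_cav + V_myo) / V_cav) ** (2.0 / 3.0) - 1.0)


def finite_difference_rate(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Central-difference time derivative, one-sided at the endpoints."""
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    if t.shape != x.shape:
        raise ValueError("t and x must have equal length")
    return np.gradient(x, t)


def laplace_power(
    t: np.ndarray,
    sigma: np.ndarray,
    V_myo,
    r: np.ndarray,
    R: np.ndarray,
    r0: Optional[float] = None,
    R0: Optional[float] = None,
    half_strain_rate: bool = False,
) -> np.ndarray:
    """Laplace power estimate P_int,* in W.

    ``V_myo sigma (rdot/r0 + Rdot/R0)`` with radii rates from central
    finite differences and rates normalized by the reference radii
    (defaulting to the first sample).  ``half_strain_rate`` exposes the
    alternative convention in which the bracket is averaged over the two
    in-plane directions instead of summed.
    """
    t = np.asarray(t, float)
    r = np.asarray(r, float)
    R = np.asarray(R, float)
    if r0 is None:
        r0 = float(r[0])
    if R0 is None:
        R0 = float(R[0])
    _require_positive(r0=r0, R0=R0)
    rate = finite_difference_rate(t, r) / r0 + finite_difference_rate(t, R) / R0
    if half_strain_rate:
        rate = 0.5 * rate
    return np.asarray(V_myo, float) * np.asarray(sigma, float) * rate  # kPa ml/ms = W


def work_from_power(t: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid integral of a power trace: W(t) in J, W(t0)=0."""
    t = np.asarray(t, float)
    P = np.asarray(P, float)
    out = np.zeros_like(P)
    out[1:] = np.cumsum(0.5 * (P[1:] + P[:-1]) * np.diff(t))
    return out * 1e-3  # W * ms -> J


def ihw_ihp(V_myo: float, sigma: float, T_sct: float):
    """Internal heart work (J) and power (W) indicators.

    IHW = V_myo * sigma interprets wall volume times Laplace stress as
    stored mechanical potential energy; IHP = IHW / T_sct spreads it over
    the systolic contraction time (ms), the interval from end-diastole to
    peak stress.  Relative indicators, not physical power measurements.
    """
    if T_sct <= 0:
        raise ValueError("contraction time must be positive")
    ihw = V_myo * sigma * J_PER_KPA_ML
    return ihw, ihw / (T_sct * 1e-3)


def hydrodynamic_power(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """P_ext = p * q in W (p in kPa, outflow q = dV_cav/dt in ml/ms)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("pressure and flow traces must have equal length")
    return p * q


def ehp(t: np.ndarray, p_ao: np.ndarray, q: np.ndarray, window) -> float:
    """External heart power (W): systolic time average of p_ao * q.

    ``window = (t_start, t_end)`` delimits systole; approximately equal to
    MAP x CO for physiological pulse shapes.
    """
    t = np.asarray(t, float)
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 2:
        raise ValueError("empty systolic window")
    ts = t[mask]
    integrand = np.asarray(p_ao, float)[mask] * np.asarray(q, float)[mask]
    return float(np.trapezoid(integrand, ts) / (ts[-1] - ts[0]))


def power_efficiency(EHP: float, P_peak: float) -> float:
    """Ratio of delivered external power to peak power, as a magnitude.

    Used both for the physical definition (P_peak = peak internal or
    external power) and the clinical one (P_peak = IHP).
    """
    if P_peak == 0:
        raise ZeroDivisionError("peak power must be nonzero")
    return abs(EHP) / abs(P_peak)


def mean_arterial_pressure(p_dia: float, p_sys: float) -> float:
    """Cuff-based MAP estimate p_dia + (p_sys - p_dia)/3 (same units in/out)."""
    return p_dia + (p_sys - p_dia) / 3.0


@dataclass
class LaplaceSeries:
    """Time-aligned Laplace stress / power / work estimates for one cycle."""

    t: np.ndarray
    sigma_h: np.ndarray
    sigma_H: np.ndarray
    sigma_V: np.ndarray
    P_int_h: np.ndarray
    P_int_H: np.ndarray
    P_int_V: np.ndarray
    W_int_h: np.ndarray
    W_int_H: np.ndarray
    W_int_V: np.ndarray

    @classmethod
    def from_inputs(
        cls,
        t: np.ndarray,
        p: np.ndarray,
        r: np.ndarray,
        R: np.ndarray,
        V_cav: np.ndarray,
        V_myo,
        r0: Optional[float] = None,
        R0: Optional[float] = None,
    ) -> "LaplaceSeries":
        h = np.asarray(R, float) - np.asarray(r, float)
        s_h = sigma_thin(p, r, h)
        s_H = sigma_thick(p, r, h)
        s_V = sigma_volume(p, V_cav, V_myo)
        kw = dict(V_myo=V_myo, r=r, R=R, r0=r0, R0=R0)
        P_h = laplace_power(t, s_h, **kw)
        P_H = laplace_power(t, s_H, **kw)
        P_V = laplace_power(t, s_V, **kw)
        return cls(
            t=np.asarray(t, float),
            sigma_h=s_h,
            sigma_H=s_H,
            sigma_V=s_V,
            P_int_h=P_h,
            P_int_H=P_H,
            P_int_V=P_V,
            W_int_h=work_from_power(t, P_h),
            W_int_H=work_from_power(t, P_H),
            W_int_V=work_from_power(t, P_V),
        )


@dataclass
class PowerSummary:
    """Peak-power and efficiency summary for one simulated cycle (W, J)."""

    P_int_peak: float
    P_int_at_peak_pressure: float
    P_ext_peak: float
    P_ext_at_peak_pressure: float
    p_peak_times_q_peak: float
    P_int_h_at_peak_pressure: float
    P_int_H_at_peak_pressure: float
    P_int_V_at_peak_pressure: float
    IHW: float
    IHP: float
    EHP: float
    P_eff: float
    P_eff_clin: float
    T_sct: float

    def to_dict(self) -> dict:
        return asdict(self)
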