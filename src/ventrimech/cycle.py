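"""Lumped left-ventricular cycle simulator (synthetic-data generator).

The LV is an incompressible thick-walled Demiray sphere with a uniform
active in-plane tension transient, ejecting against a three-element
Windkessel (valve impedance Z_v in series with the characteristic aortic
impedance Z_a, peripheral resistance R_art and compliance C_art).  One
heartbeat is integrated with an operator-split per phase:

* IVC: cavity radius frozen; luminal pressure rises with active tension
  until it reaches aortic pressure;
* ejection: at each step an implicit balance
  ``p_sphere(r, S_a) = p_ao + Z_v q`` with ``q = -dV_cav/dt`` is solved by
  a bracketed root-find; the valve closes when forward flow ceases;
* IVR: radius frozen while the active transient decays;
* filling: a quasi-static luminal pressure ramp back to the end-diastolic
  pressure closes the loop at the end of the cycle period.

The simulator reproduces the statistical structure of clinical pretreatment
records of aortic-stenosis patients (cavity volumes, cuff pressures, heart
rate, transvalvular gradient); those records and the fitted Windkessel /
active-stress parameters are embedded as the default study conditions.

Units follow the package convention (kPa, mm, ms, ml); patient records are
in clinical units (mmHg, min^-1) and converted on entry.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .constitutive import ActiveStressParams, MaterialDemiray, active_tension_trace
from .sphere import (
    InflationState,
    SolverError,
    SphereGeometry,
    _state_from_inner_radius,
    inflate,
    pressure_from_inner_radius,
)
from .slicing import SurfacePair
from .units import MM3_PER_ML, bpm_to_period_ms, mmhg_to_kpa

import trimesh

__all__ = [
    "PatientRecord",
    "WindkesselParams",
    "CycleConfig",
    "HemodynamicTrace",
    "PATIENTS",
    "WINDKESSEL",
    "derive_record_fields",
    "sphere_radius_from_volume",
    "windkessel_step",
    "simulate_cycle",
    "config_from_patient",
    "emit_surfaces",
    "add_measurement_noise",
]


@dataclass(frozen=True)
class PatientRecord:
    """Pretreatment clinical record (volumes ml, pressures mmHg, HR 1/min)."""

    EDV: float
    ESV: float
    HR: float
    p_dia: float
    p_sys: float
    h_septum: float
    h_lateral: float
    delta_p: float = 0.0

    @property
    def SV(self) -> float:
        return self.EDV - self.ESV

    @property
    def EF(self) -> float:
        return 100.0 * self.SV / self.EDV

    @property
    def MAP(self) -> float:
        return self.p_dia + (self.p_sys - self.p_dia) / 3.0

    @property
    def h_mean(self) -> float:
        return 0.5 * (self.h_septum + self.h_lateral)


#: Pretreatment aortic-stenosis patient characteristics (clinical units).
PATIENTS: Dict[str, PatientRecord] = {
    "A": PatientRecord(112.0, 46.0, 53, 74, 126, 12.0, 12.5, 95),
    "B": PatientRecord(121.0, 54.7, 81, 75, 134, 11.2, 13.8, 62),
    "C": PatientRecord(118.2, 42.2, 75, 71, 141, 16.0, 18.2, 79),
    "D": PatientRecord(172.0, 103.0, 68, 79, 144, 14.0, 15.2, 59),
}


@dataclass(frozen=True)
class WindkesselParams:
    """Three-element afterload (impedances kPa.ms/ml, compliance ml/kPa)."""

    Z_v: float
    Z_a: float
    R_art: float
    C_art: float

    def __post_init__(self) -> None:
        if min(self.Z_v, self.Z_a, self.R_art, self.C_art) <= 0:
            raise ValueError("Windkessel parameters must be positive")

    @property
    def tau(self) -> float:
        """Diastolic decay time constant R_art * C_art in ms."""
        return self.R_art * self.C_art


#: Fitted afterload parameters per patient.
WINDKESSEL: Dict[str, WindkesselParams] = {
    "A": WindkesselParams(35.82, 26.00, 187.74, 15.23),
    "B": WindkesselParams(16.08, 11.03, 72.65, 26.62),
    "C": WindkesselParams(15.93, 12.78, 77.34, 25.50),
    "D": WindkesselParams(22.34, 11.09, 62.73, 30.93),
}

#: Fitted active-stress parameters per patient (S_peak kPa, tau_c ms).
ACTIVE_FITS: Dict[str, Tuple[float, float]] = {
    "A": (69.0, 80.0),
    "B": (85.0, 35.0),
    "C": (63.0, 40.0),
    "D": (98.0, 58.0),
}


def derive_record_fields(EDV: float, ESV: float, HR: float, p_dia: float, p_sys: float):
    """(SV ml, EF %, MAP mmHg, CO ml/min) from raw record entries."""
    if EDV <= 0:
        raise ValueError("EDV must be positive")
    if not EDV > ESV >= 0:
        raise ValueError("need EDV > ESV >= 0")
    SV = EDV - ESV
    EF = 100.0 * SV / EDV
    MAP = p_dia + (p_sys - p_dia) / 3.0
    CO = SV * HR
    return SV, EF, MAP, CO


def sphere_radius_from_volume(V_ml: float) -> float:
    """Radius (mm) of a sphere holding V_ml millilitres."""
    return float(np.cbrt(3.0 * V_ml * MM3_PER_ML / (4.0 * np.pi)))


@dataclass(frozen=True)
class CycleConfig:
    """Full configuration of one synthetic heartbeat."""

    geometry: SphereGeometry
    passive: MaterialDemiray
    active: ActiveStressParams
    wk: WindkesselParams
    edp: float = 1.33  # kPa
    period: float = 1000.0  # ms
    dt: float = 1.0  # ms
    p_ao_init: float = 10.0  # kPa, aortic pressure at end-diastole
    fill_floor: float = 0.5  # kPa, LV pressure at which filling restarts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt > 1.0:
            raise ValueError("timestep must be <= 1 ms")


@dataclass
class HemodynamicTrace:
    """Time-aligned hemodynamic record of one simulated beat.

    ``q`` is aortic outflow (= -dV_cav/dt during ejection, 0 otherwise,
    ml/ms); ``phase`` labels each sample as filling/IVC/ejection/IVR.
    """

    t: np.ndarray
    p_lv: np.ndarray
    p_ao: np.ndarray
    V_cav: np.ndarray
    q: np.ndarray
    r: np.ndarray
    R: np.ndarray
    S_a: np.ndarray
    phase: np.ndarray
    config: CycleConfig
    events: Dict[str, float] = field(default_factory=dict)

    @property
    def V_myo(self) -> float:
        """Wall volume in ml (exactly conserved)."""
        return self.config.geometry.wall_volume

    @property
    def EDV(self) -> float:
        return float(self.V_cav[0])

    @property
    def ESV(self) -> float:
        return float(self.V_cav.min())

    @property
    def EF(self) -> float:
        return 100.0 * (self.EDV - self.ESV) / self.EDV

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": self.t,
                "p_lv_kPa": self.p_lv,
                "p_ao_kPa": self.p_ao,
                "V_cav_ml": self.V_cav,
                "q_ml_per_ms": self.q,
                "r_mm": self.r,
                "R_mm": self.R,
                "S_a_kPa": self.S_a,
                "phase": self.phase,
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def state_at(self, i: int) -> InflationState:
        """Ground-truth radial stress state at sample i (profiles included)."""
        return _state_from_inner_radius(
            self.config.geometry, self.config.passive, float(self.r[i]), float(self.S_a[i])
        )


def windkessel_step(p_c: float, q: float, dt: float, wk: WindkesselParams) -> Tuple[float, float]:
    """One implicit-Euler step of the arterial compartment.

    Returns (new compartment pressure p_c, aortic root pressure p_ao) for
    outflow q over dt.  With q = 0 the compartment decays exponentially
    with time constant R_art * C_art.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p_c_new = (p_c + dt / wk.C_art * q) / (1.0 + dt / (wk.R_art * wk.C_art))
    return p_c_new, p_c_new + wk.Z_a * q


class _SpherePressure:
    """Cached passive pressure p_pas(r) of the shell plus active term."""

    def __init__(self, geom: SphereGeometry, mat: MaterialDemiray, n_grid: int = 900):
        self.geom = geom
        self.r_min, self.r_max = 0.42 * geom.r0, 1.9 * geom.r0
        r_grid = np.linspace(self.r_min, self.r_max, n_grid)
        p_grid = [pressure_from_inner_radius(geom, mat, r) for r in r_grid]
        self._spline = CubicSpline(r_grid, p_grid)

    def __call__(self, r: float, S_a: float) -> float:
        R = self.geom.outer_from_inner(r)
        return float(self._spline(r)) + 2.0 * S_a * np.log(R / r)


_PRESSURE_CACHE: Dict[Tuple[SphereGeometry, MaterialDemiray], _SpherePressure] = {}


def _sphere_pressure(geom: SphereGeometry, mat: MaterialDemiray) -> _SpherePressure:
    key = (geom, mat)
    if key not in _PRESSURE_CACHE:
        if len(_PRESSURE_CACHE) > 32:
            _PRESSURE_CACHE.clear()
        _PRESSURE_CACHE[key] = _SpherePressure(geom, mat)
    return _PRESSURE_CACHE[key]


def _expanding_root(f, x0: float, step: float, lo_min: float, hi_max: float) -> float:
    """Bracketed root of f near x0, expanding the bracket outward."""
    f0 = f(x0)
    if f0 == 0.0:
        return x0
    direction = -1.0 if f0 > 0.0 else 1.0
    a, fa = x0, f0
    x = x0
    for _ in range(400):
        x = min(max(x + direction * step, lo_min), hi_max)
        fx = f(x)
        if fa * fx <= 0.0:
            lo, hi = (x, a) if x < a else (a, x)
            return brentq(f, lo, hi, xtol=1e-10)
        a, fa = x, fx
        if x in (lo_min, hi_max):
            break
    raise SolverError("bracketed root search failed")


def _cavity_volume(r: float) -> float:
    return 4.0 / 3.0 * np.pi * r ** 3 / MM3_PER_ML


def simulate_cycle(cfg: CycleConfig) -> HemodynamicTrace:
    """Integrate one heartbeat; see module docstring for the phase logic.

    Deterministic: bit-reproducible for a fixed configuration.  Raises
    :class:`ventrimech.sphere.SolverError` if an implicit ejection step
    fails to converge.
    """
    geom, mat, act, wk = cfg.geometry, cfg.passive, cfg.active, cfg.wk
    p_of_r = _sphere_pressure(geom, mat)
    r_ed = inflate(geom, mat, cfg.edp).r

    n = int(round(cfg.period / cfg.dt)) + 1
    t = cfg.dt * np.arange(n)
    S_a = active_tension_trace(t, act)
    r_tr = np.empty(n)
    p_lv = np.empty(n)
    p_ao = np.empty(n)
    q_tr = np.zeros(n)
    phase = np.empty(n, dtype=object)

    r_cur = r_ed
    p_c = cfg.p_ao_init
    mode = "IVC"
    events: Dict[str, float] = {}
    fill_p0 = cfg.fill_floor
    fill_t0 = 0.0
    dt = cfg.dt

    r_tr[0] = r_cur
    p_lv[0] = cfg.edp
    p_ao[0] = p_c
    phase[0] = "IVC"

    for i in range(1, n):
        Sa = float(S_a[i])

        # --- phase transitions, evaluated on the trial (q = 0) step -------
        if mode == "IVC":
            _, pao_trial = windkessel_step(p_c, 0.0, dt, wk)
            if p_of_r(r_cur, Sa) >= pao_trial:
                mode = "ejection"
                events.setdefault("t_0_ej", float(t[i]))
        if mode == "ejection":
            V_n = _cavity_volume(r_cur)
            p_c_frozen = p_c

            def resid(r_new):
                q = (V_n - _cavity_volume(r_new)) / dt  # ml/ms, >= 0 for outflow
                _, pao_new = windkessel_step(p_c_frozen, q, dt, wk)
                return p_of_r(r_new, Sa) - (pao_new + wk.Z_v * q)

            if resid(r_cur) <= 0.0:  # forward flow would reverse: valve closes
                mode = "IVR"
                events.setdefault("t_ES", float(t[i]))
        if mode == "IVR":
            _, pao_trial = windkessel_step(p_c, 0.0, dt, wk)
            plv_trial = p_of_r(r_cur, Sa)
            if plv_trial <= cfg.fill_floor or Sa <= 1e-6 * max(act.S_peak, 1.0):
                mode = "filling"
                fill_p0 = max(min(plv_trial, cfg.edp), 0.0)
                fill_t0 = float(t[i])

        # --- single committed step per sample -----------------------------
        if mode == "ejection":
            r_new = _expanding_root(
                resid, r_cur, max(0.01 * geom.r0, 1e-3), p_of_r.r_min, r_cur
            )
            q = (V_n - _cavity_volume(r_new)) / dt
            p_c, pao = windkessel_step(p_c, q, dt, wk)
            r_cur = r_new
            q_tr[i] = q
            plv = pao + wk.Z_v * q
        elif mode == "filling":
            p_c, pao = windkessel_step(p_c, 0.0, dt, wk)
            frac = (t[i] - fill_t0) / max(cfg.period - fill_t0, dt)
            plv = fill_p0 + (cfg.edp - fill_p0) * min(frac, 1.0)
            r_cur = _expanding_root(
                lambda r_new: p_of_r(r_new, Sa) - plv,
                r_cur,
                max(0.01 * geom.r0, 1e-3),
                p_of_r.r_min,
                p_of_r.r_max,
            )
        else:  # IVC or IVR: isovolumetric, radius frozen
            p_c, pao = windkessel_step(p_c, 0.0, dt, wk)
            plv = p_of_r(r_cur, Sa)

        r_tr[i] = r_cur
        p_lv[i] = plv
        p_ao[i] = pao
        phase[i] = mode

    V_cav = 4.0 / 3.0 * np.pi * r_tr ** 3 / MM3_PER_ML
    R_tr = np.cbrt(geom.R0 ** 3 - geom.r0 ** 3 + r_tr ** 3)
    events["t_p_hat"] = float(t[int(np.argmax(p_lv))])
    trace = HemodynamicTrace(
        t=t,
        p_lv=p_lv,
        p_ao=p_ao,
        V_cav=V_cav,
        q=q_tr,
        r=r_tr,
        R=R_tr,
        S_a=S_a,
        phase=phase,
        config=cfg,
        events=events,
    )
    return trace


def config_from_patient(
    rec: PatientRecord,
    wk: WindkesselParams,
    passive: Optional[MaterialDemiray] = None,
    tau_c: float = 80.0,
    t_dur: float = 300.0,
    tau_r: float = 30.0,
    edp: float = 1.33,
    dt: float = 1.0,
    ef_tol: float = 0.05,
    s_peak_max: float = 500.0,
) -> CycleConfig:
    """Build a cycle configuration reproducing a patient record.

    The reference shell is sized so that the cavity volume *at* the
    end-diastolic pressure equals the record's EDV (sphere-volume
    arithmetic plus a root-find for the diastolic unloading), the wall
    volume matches the record's mean equatorial wall thickness, and the
    peak active tension is found by bisection so the simulated ejection
    fraction lands within ``ef_tol`` (relative) of the record's EF.
    """
    passive = passive or MaterialDemiray(a=2.0, b=8.0)
    r_ed = sphere_radius_from_volume(rec.EDV)
    R_ed = r_ed + rec.h_mean
    wall = R_ed ** 3 - r_ed ** 3  # mm^3 * 3/(4 pi), conserved

    def geom_for(r0: float) -> SphereGeometry:
        return SphereGeometry(r0, float(np.cbrt(r0 ** 3 + wall)))

    def ed_mismatch(r0: float) -> float:
        return inflate(geom_for(r0), passive, edp, n_profile=101).r - r_ed

    r0 = brentq(ed_mismatch, 0.55 * r_ed, r_ed, xtol=1e-9)
    geom = geom_for(r0)
    period = bpm_to_period_ms(rec.HR)

    base = CycleConfig(
        geometry=geom,
        passive=passive,
        active=ActiveStressParams(S_peak=0.0, tau_c=tau_c, tau_r=tau_r, t_dur=t_dur),
        wk=wk,
        edp=edp,
        period=period,
        dt=dt,
        p_ao_init=mmhg_to_kpa(rec.p_dia),
    )
    if rec.EF <= 0:
        return base

    def ef_at(s_peak: float) -> float:
        if s_peak == 0:
            return 0.0
        cfg = replace(base, active=replace(base.active, S_peak=s_peak))
        return simulate_cycle(cfg).EF

    target = rec.EF
    lo, hi = 0.0, 60.0
    while ef_at(hi) < target:
        hi *= 1.6
        if hi > s_peak_max:
            raise SolverError(f"EF target {target:.1f}% unreachable below S_peak={s_peak_max}")
    ef_lo, ef_hi = 0.0, ef_at(hi)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        ef_mid = ef_at(mid)
        if abs(ef_mid - target) / target <= 0.2 * ef_tol:
            lo = hi = mid
            break
        if ef_mid < target:
            lo = mid
        else:
            hi = mid
    s_peak = 0.5 * (lo + hi)
    cfg = replace(base, active=replace(base.active, S_peak=s_peak))
    ef = simulate_cycle(cfg).EF
    if abs(ef - target) / target > ef_tol:
        raise SolverError(
            f"EF fitting did not converge: achieved {ef:.2f}% vs target {target:.2f}%"
        )
    return cfg


# ---------------------------------------------------------------------------
# surface emission and measurement noise
# ---------------------------------------------------------------------------

def emit_surfaces(
    trace: HemodynamicTrace,
    indices: Sequence[int],
    shape: str = "prolate",
    aspect: float = 1.8,
    subdivisions: int = 3,
    long_axis_exponent: float = 0.15,
) -> List[SurfacePair]:
    """Endo/epi surface meshes consistent with the cavity-volume trace.

    ``shape='sphere'`` emits concentric icospheres at the exact deformed
    radii; ``shape='prolate'`` emits volume-matched prolate spheroids with
    LV-like kinematics: the end-diastolic long/short axis ratio is
    ``aspect`` (long axis along z) and the long semi-axis follows
    ``a(t) = a_ED * (V_cav/EDV)^long_axis_exponent``, so longitudinal
    shortening stays modest (~12% at an ejection fraction of 60%, as in a
    real ventricle) while the short axis carries most of the contraction.
    The epicardial long semi-axis adds the shell's wall width at the apex;
    its short semi-axis follows from the (conserved) wall volume.
    """
    if shape not in ("sphere", "prolate"):
        raise ValueError("shape must be 'sphere' or 'prolate'")
    unit = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v_ed_mm3 = trace.V_cav[0] * MM3_PER_ML
    a_ed = aspect * np.cbrt(v_ed_mm3 / (4.0 / 3.0 * np.pi * aspect))
    pairs = []
    for i in indices:
        v_cav_mm3 = trace.V_cav[i] * MM3_PER_ML
        v_tot_mm3 = (trace.V_cav[i] + trace.V_myo) * MM3_PER_ML
        if shape == "sphere":
            endo = unit.copy().apply_scale(trace.r[i])
            epi = unit.copy().apply_scale(trace.R[i])
        else:
            a_in = a_ed * (v_cav_mm3 / v_ed_mm3) ** long_axis_exponent
            b_in = np.sqrt(v_cav_mm3 / (4.0 / 3.0 * np.pi * a_in))
            a_out = a_in + (trace.R[i] - trace.r[i])
            b_out = np.sqrt(v_tot_mm3 / (4.0 / 3.0 * np.pi * a_out))
            endo = unit.copy()
            endo.vertices = endo.vertices * np.array([b_in, b_in, a_in])
            epi = unit.copy()
            epi.vertices = epi.vertices * np.array([b_out, b_out, a_out])
        pairs.append(SurfacePair(endo=endo, epi=epi, label=float(trace.t[i])))
    return pairs


def add_measurement_noise(trace: HemodynamicTrace, rel_sd: float, seed: Optional[int] = None) -> HemodynamicTrace:
    """Return a copy with multiplicative Gaussian noise on p and V traces.

    Noise is the only stochastic element of the generator and is injected
    exclusively through this seed-controlled call.
    """
    rng = np.random.default_rng(trace.config.seed if seed is None else seed)

    def jitter(x):
        return x * (1.0 + rel_sd * rng.standard_normal(len(x)))

    return replace(
        trace,
        p_lv=jitter(trace.p_lv),
        p_ao=jitter(trace.p_ao),
        V_cav=jitter(trace.V_cav),
    )
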