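"""Lumped LV cycle simulator: record arithmetic, afterload, phase logic."""
import numpy as np
import pytest

import ventrimech as vm
from ventrimech.cycle import (
    add_measurement_noise,
    emit_surfaces,
    sphere_radius_from_volume,
    windkessel_step,
)


# ---------------------------------------------------------------------------
# patient record arithmetic
# ---------------------------------------------------------------------------

def test_derive_record_fields_rows_a_and_d():
    SV, EF, MAP, CO = vm.derive_record_fields(112.0, 46.0, 53, 74, 126)
    assert (round(SV, 2), round(EF, 2), round(MAP, 2)) == (66.00, 58.93, 91.33)
    assert CO == pytest.approx(66.0 * 53)
    SV, EF, MAP, _ = vm.derive_record_fields(172.0, 103.0, 68, 79, 144)
    assert (round(EF, 2), round(MAP, 2)) == (40.12, 100.67)


def test_derive_record_fields_simple_ratio_and_errors():
    _, EF, _, _ = vm.derive_record_fields(100.0, 50.0, 60, 80, 120)
    assert EF == pytest.approx(50.0)
    with pytest.raises(ValueError):
        vm.derive_record_fields(0.0, 0.0, 60, 80, 120)
    with pytest.raises(ValueError):
        vm.derive_record_fields(50.0, 60.0, 60, 80, 120)


def test_patient_table_consistency():
    for rec in vm.PATIENTS.values():
        assert rec.EDV > rec.ESV > 0
        assert 0 < rec.EF < 100


def test_sphere_radius_from_edv():
    assert sphere_radius_from_volume(112.0) == pytest.approx(29.90, abs=0.01)


# ---------------------------------------------------------------------------
# Windkessel
# ---------------------------------------------------------------------------

def test_windkessel_zero_flow_decay():
    wk = vm.WINDKESSEL["A"]
    assert wk.tau == pytest.approx(187.74 * 15.23)  # decay constant 2859 ms
    p, dt = 10.0, 1.0
    p1, pao1 = windkessel_step(p, 0.0, dt, wk)
    assert p1 == pytest.approx(p / (1.0 + dt / wk.tau))
    assert pao1 == p1
    # discrete decay matches the exponential over many steps
    n = 2000
    pn = p / (1.0 + dt / wk.tau) ** n
    assert pn == pytest.approx(p * np.exp(-n * dt / wk.tau), rel=5e-4)


def test_windkessel_constant_flow_fixed_point():
    wk = vm.WINDKESSEL["B"]
    q = 0.2
    p_star = q * wk.R_art
    p1, pao = windkessel_step(p_star, q, 1.0, wk)
    assert p1 == pytest.approx(p_star, rel=1e-12)
    assert pao == pytest.approx(p_star + wk.Z_a * q, rel=1e-12)


# ---------------------------------------------------------------------------
# cycle simulation
# ---------------------------------------------------------------------------

def test_no_contraction_means_no_ejection():
    geom = vm.SphereGeometry(25.0, 37.0)
    cfg = vm.CycleConfig(
        geometry=geom,
        passive=vm.MaterialDemiray(a=2.0, b=8.0),
        active=vm.constitutive.ActiveStressParams(S_peak=0.0),
        wk=vm.WINDKESSEL["A"],
        period=800.0,
    )
    tr = vm.simulate_cycle(cfg)
    assert tr.EDV - tr.ESV == pytest.approx(0.0, abs=1e-9)
    assert np.all(tr.q == 0.0)
    assert np.allclose(tr.p_lv, cfg.edp, atol=1e-9)


def test_ef_fit_hits_record_target(patient_a_config, patient_a_trace):
    target = vm.PATIENTS["A"].EF
    assert abs(patient_a_trace.EF - target) / target < 0.05
    assert patient_a_config.active.S_peak > 0


def test_trace_invariants(patient_a_trace):
    tr = patient_a_trace
    phases = np.asarray(tr.phase)
    wk = tr.config.wk
    # isovolumetric phases: cavity volume frozen exactly
    for ph in ("IVC", "IVR"):
        V = tr.V_cav[phases == ph]
        assert np.max(np.abs(V - V[0])) / V[0] < 1e-12
    ej = phases == "ejection"
    assert np.all(tr.q[ej] >= 0.0)
    # transvalvular gradient follows the valve impedance during ejection
    dp = tr.p_lv[ej] - tr.p_ao[ej]
    assert np.allclose(dp, wk.Z_v * tr.q[ej], rtol=1e-9, atol=1e-12)
    assert np.all(tr.q[~ej] == 0.0)
    # peak LV pressure occurs after the onset of ejection
    assert tr.events["t_p_hat"] > tr.events["t_0_ej"]
    # peak transvalvular gradient at peak flow
    assert np.argmax(tr.p_lv - tr.p_ao) == np.argmax(tr.q)
    # wall volume is exactly conserved by the incompressible kinematics
    v_wall = 4.0 / 3.0 * np.pi * (tr.R ** 3 - tr.r ** 3) / 1000.0
    assert np.max(np.abs(v_wall - tr.V_myo)) / tr.V_myo < 1e-12
    # cycle closes at the end-diastolic pressure (last sample within one
    # timestep of the exact period end)
    assert tr.p_lv[-1] == pytest.approx(tr.config.edp, rel=1e-3)


def test_trace_is_reproducible(patient_a_config):
    a = vm.simulate_cycle(patient_a_config)
    b = vm.simulate_cycle(patient_a_config)
    assert np.array_equal(a.p_lv, b.p_lv)
    assert np.array_equal(a.V_cav, b.V_cav)


def test_measurement_noise_is_seed_controlled(patient_a_trace):
    n1 = add_measurement_noise(patient_a_trace, 0.01, seed=7)
    n2 = add_measurement_noise(patient_a_trace, 0.01, seed=7)
    n3 = add_measurement_noise(patient_a_trace, 0.01, seed=8)
    assert np.array_equal(n1.p_lv, n2.p_lv)
    assert not np.array_equal(n1.p_lv, n3.p_lv)
    assert np.array_equal(n1.t, patient_a_trace.t)  # time base untouched


def test_peak_pressure_plausible(patient_a_trace):
    # aortic-stenosis loading: LV systolic pressure well above cuff systolic
    p_peak_mmhg = patient_a_trace.p_lv.max() / 0.133322
    assert 150.0 < p_peak_mmhg < 350.0
    # transvalvular gradient is substantial
    dp_mmhg = (patient_a_trace.p_lv - patient_a_trace.p_ao).max() / 0.133322
    assert dp_mmhg > 30.0


def test_config_from_patient_matches_ed_volume(patient_a_config):
    tr_edv = vm.simulate_cycle(patient_a_config).EDV
    assert tr_edv == pytest.approx(112.0, rel=1e-6)


def test_emitted_surfaces_match_volume_trace(patient_a_trace):
    idx = [0, 300]
    for shape, tol in (("sphere", 0.01), ("prolate", 0.01)):
        pairs = emit_surfaces(patient_a_trace, idx, shape=shape)
        for k, i in enumerate(idx):
            v_mesh = pairs[k].endo.volume / 1000.0
            assert v_mesh == pytest.approx(patient_a_trace.V_cav[i], rel=tol)
            v_wall = (pairs[k].epi.volume - pairs[k].endo.volume) / 1000.0
            assert v_wall == pytest.approx(patient_a_trace.V_myo, rel=tol)


def test_trace_csv_roundtrip(tmp_path, patient_a_trace):
    path = tmp_path / "trace.csv"
    patient_a_trace.write_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert np.allclose(df["p_lv_kPa"], patient_a_trace.p_lv)
    assert list(df.columns[:7]) == [
        "t_ms", "p_lv_kPa", "p_ao_kPa", "V_cav_ml", "q_ml_per_ms", "r_mm", "R_mm",
    ]
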