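"""Shared fixtures: benchmark materials/geometries and the (expensive)
patient-like cycle comparison, computed once per session."""
import numpy as np
import pytest

import ventrimech as vm
from ventrimech.pipeline import run_cycle_comparison, run_sphere_verification


@pytest.fixture(scope="session")
def benchmark_material():
    return vm.MaterialDemiray(a=10.0, b=8.0)


@pytest.fixture(scope="session")
def verification():
    """Penalty-formulation sphere verification rows and error report."""
    rows, errors = run_sphere_verification(formulation="penalty")
    return {r.model: r for r in rows}, errors


@pytest.fixture(scope="session")
def patient_a_config():
    rec = vm.PATIENTS["A"]
    return vm.config_from_patient(rec, vm.WINDKESSEL["A"], tau_c=80.0)


@pytest.fixture(scope="session")
def patient_a_trace(patient_a_config):
    return vm.simulate_cycle(patient_a_config)


@pytest.fixture(scope="session")
def patient_a_comparison(patient_a_config):
    return run_cycle_comparison(patient_a_config, mesh_shape="prolate", stride_ms=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
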