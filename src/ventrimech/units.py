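"""Unit conventions and conversion factors.

All internal computations use a consistent mechanical unit system:

* stress / pressure : kPa
* length            : mm
* time              : ms
* volume            : ml (= 1000 mm^3)

In this system ``kPa * ml / ms`` equals exactly one watt, and
``kPa * ml`` equals one millijoule, which keeps power and work bookkeeping
free of hidden factors.  Clinical units (mmHg, beats/min, ml/s) are
converted only at I/O boundaries.
"""

#: 1 mmHg in kPa
MMHG_TO_KPA = 0.133322

#: 1 kPa in mmHg
KPA_TO_MMHG = 1.0 / MMHG_TO_KPA

#: mm^3 per ml
MM3_PER_ML = 1000.0

#: joules per (kPa * ml): 1 kPa * 1 ml = 1e3 Pa * 1e-6 m^3 = 1e-3 J
J_PER_KPA_ML = 1.0e-3

#: watts per (kPa * ml / ms): 1e-3 J / 1e-3 s = 1 W
W_PER_KPA_ML_MS = 1.0


def mmhg_to_kpa(p: float) -> float:
    return p * MMHG_TO_KPA


def kpa_to_mmhg(p: float) -> float:
    return p * KPA_TO_MMHG


def bpm_to_period_ms(hr: float) -> float:
    """Heart rate in min^-1 to cycle period in ms."""
    return 60000.0 / hr
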