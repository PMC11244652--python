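"""Unit conversions used across the package.

All internal physics is SI (m, s, Pa, m^3/s); user-facing interfaces speak the
units the field reports in: micrometres for geometry, mL/min or uL/min for
flow, mPa*s for viscosity, dyn/cm^2 for wall shear stress.
"""

UM_TO_M = 1e-6
M_TO_UM = 1e6

MPAS_TO_PAS = 1e-3

ML_PER_MIN_TO_M3_PER_S = 1e-6 / 60.0
UL_PER_MIN_TO_M3_PER_S = 1e-9 / 60.0

PA_TO_DYN_PER_CM2 = 10.0  # 1 dyn/cm^2 = 0.1 Pa


def um_to_m(x: float) -> float:
    return x * UM_TO_M


def ml_min_to_m3_s(q: float) -> float:
    return q * ML_PER_MIN_TO_M3_PER_S


def m3_s_to_ul_min(q: float) -> float:
    return q / UL_PER_MIN_TO_M3_PER_S


def pa_to_dyn_cm2(p: float) -> float:
    return p * PA_TO_DYN_PER_CM2
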