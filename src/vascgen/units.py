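"""Unit conversions between physiological and SI units.

All internal computation is carried out in SI (m, Pa, Pa s, m^3 s^-1); the
public API and all file formats speak the conventional physiological units
(mm, mm Hg, cP, ml min^-1).  Converting once at the boundary keeps the
fourth-power radius terms of Poiseuille's law free of unit bugs.
"""

MMHG_TO_PA = 133.322387415
CP_TO_PAS = 1.0e-3
MLMIN_TO_M3S = 1.0e-6 / 60.0
MM_TO_M = 1.0e-3
CM_TO_M = 1.0e-2
CM3_TO_M3 = 1.0e-6


def mmhg_to_pa(p: float) -> float:
    return p * MMHG_TO_PA


def pa_to_mmhg(p: float) -> float:
    return p / MMHG_TO_PA


def cp_to_pas(eta: float) -> float:
    return eta * CP_TO_PAS


def pas_to_cp(eta: float) -> float:
    return eta / CP_TO_PAS


def mlmin_to_m3s(q: float) -> float:
    return q * MLMIN_TO_M3S


def mm_to_m(x: float) -> float:
    return x * MM_TO_M


def m_to_mm(x: float) -> float:
    return x / MM_TO_M
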