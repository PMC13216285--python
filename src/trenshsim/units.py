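"""Unit conversions.

All internal computation is in CGS units (cm, poise, dyn/cm^2 for pressure,
cm^3/s for volumetric flow).  Clinical units (mmHg, mL/min) appear only at
API boundaries, through the converters below.
"""

#: dyn/cm^2 per mmHg
MMHG = 1333.22

#: mL/min per cm^3/s
CM3S_TO_ML_MIN = 60.0


def mmhg_to_cgs(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to dyn/cm^2."""
    return p_mmhg * MMHG


def cgs_to_mmhg(p_cgs: float) -> float:
    """Convert a pressure from dyn/cm^2 to mmHg."""
    return p_cgs / MMHG


def cm3s_to_ml_min(q: float) -> float:
    """Convert a volumetric flow from cm^3/s to mL/min."""
    return q * CM3S_TO_ML_MIN
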