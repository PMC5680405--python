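"""Unit conversions.

All transport math inside the package runs in cgs (cm, s, cm^3); public
constructors accept the units practitioners quote (uL/min, h^-1, mL, Da)
and convert once at the boundary.
"""

UL_PER_MIN_TO_CM3_PER_S = 1e-3 / 60.0  # 1 uL/min = 1e-3 cm^3 / 60 s
ML_TO_CM3 = 1.0  # 1 mL = 1 cm^3
PER_HOUR_TO_PER_S = 1.0 / 3600.0
HOUR_TO_S = 3600.0
MIN_TO_S = 60.0
DAY_TO_HOUR = 24.0


def ul_per_min_to_cm3_per_s(q: float) -> float:
    return q * UL_PER_MIN_TO_CM3_PER_S


def per_hour_to_per_s(k: float) -> float:
    return k * PER_HOUR_TO_PER_S


def hours_to_seconds(t: float) -> float:
    return t * HOUR_TO_S


def seconds_to_hours(t: float) -> float:
    return t / HOUR_TO_S
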