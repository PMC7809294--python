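"""Unit conversion helpers.

All internal quantities are SI (meters, seconds, volts, kelvin-sized Celsius
degrees).  Configuration files use the field's customary units: millimeters
for geometry, V/cm for voltage-to-distance ratios, microseconds for H-FIRE
phase widths.
"""

MM = 1e-3          # m per mm
CM = 1e-2          # m per cm
US = 1e-6          # s per microsecond
V_PER_CM = 100.0   # (V/m) per (V/cm)


def mm_to_m(x):
    return x * MM


def m_to_mm(x):
    return x / MM


def v_per_cm_to_v_per_m(x):
    return x * V_PER_CM


def v_per_m_to_v_per_cm(x):
    return x / V_PER_CM
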