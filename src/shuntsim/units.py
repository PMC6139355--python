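"""Unit conversion constants.

All internal computation is in SI (m, s, kg, Pa, m^3); the public API uses
clinical units (mmHg, mL, l/min, cm^2, mm).
"""

MMHG = 133.322          # Pa per mmHg
KPA = 1000.0            # Pa per kPa
ML = 1e-6               # m^3 per mL
LMIN = 1e-3 / 60.0      # m^3/s per l/min
CM2 = 1e-4              # m^2 per cm^2
MM = 1e-3               # m per mm
RHO_BLOOD = 1050.0      # kg/m^3
KPA_TO_MMHG = KPA / MMHG            # 7.50062
J_PER_MMHG_ML = MMHG * ML           # 1.33322e-4 J per mmHg*mL
# resistance: mmHg per (l/min) -> Pa*s/m^3
R_CLIN = MMHG / LMIN
# compliance: mL/mmHg -> m^3/Pa
C_CLIN = ML / MMHG
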