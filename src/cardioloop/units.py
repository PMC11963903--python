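"""Unit conversion constants.

The model works in SI internally (m3, m3/s, Pa, s, m, N/m).  All public
interfaces use the conventional clinical/physiological units: ml, L/min,
mmHg, kPa, cm2, um, ms.  Multiply an interface value by the constant to get
SI; divide to go back.
"""

MMHG = 133.322387415   # Pa per mmHg
KPA = 1.0e3            # Pa per kPa
ML = 1.0e-6            # m3 per ml
LMIN = 1.0e-3 / 60.0   # m3/s per L/min
CM2 = 1.0e-4           # m2 per cm2
CM = 1.0e-2            # m per cm
UM = 1.0e-6            # m per um
MS = 1.0e-3            # s per ms
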