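"""Unit conventions and conversion constants.

Canonical internal units throughout the package: volumes in L, flows and
clearances in L/h, time in h, amounts in mg, concentrations in mg/L
(numerically identical to ug/mL). Physiology tables are stored on disk in
their tabulated units (mL, mL/s) and converted exactly once at load time;
the conversion is guarded by an explicit unit tag so it cannot be applied
twice.
"""

ML_TO_L = 1e-3
ML_PER_S_TO_L_PER_H = 3.6  # 1 mL/s = 3.6 L/h

TABLE_UNITS = "table"          # volumes mL, flows mL/s (on-disk convention)
CANONICAL_UNITS = "canonical"  # volumes L, flows L/h
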