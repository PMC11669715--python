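"""Fit a plasmid standard curve and call gene copy numbers from Ct values.

Builds a noise-free 10-fold dilution series for a perfectly efficient
assay, fits the log-linear curve, and calls copy number for a hemizygous
sample measured in a duplex reaction against the 2-copy APOB reference.
"""

import numpy as np

from gstnull import (
    DilutionSeries,
    QpcrMeasurement,
    compute_rq,
    estimate_copy_number,
    fit_standard_curve,
)

SLOPE, INTERCEPT = -3.321928, 40.0  # perfect doubling per cycle

series = DilutionSeries(
    quantities=tuple(10.0**k for k in range(1, 6)),
    ct_replicates=tuple((INTERCEPT + SLOPE * k,) for k in range(1, 6)),
)
curve = fit_standard_curve(series)
print(f"standard curve: slope {curve.slope:.4f}, intercept {curve.intercept:.1f}, "
      f"efficiency {curve.efficiency:.3f}, r^2 {curve.r_squared:.4f}")
# slope -3.32 <=> 100% amplification efficiency (template doubles each cycle)

# one GSTM1 copy -> half the APOB template -> one extra cycle to threshold
gstm1 = QpcrMeasurement("tumor1", "GSTM1", tuple(
    INTERCEPT + SLOPE * np.log10(50.0) for _ in range(3)
))
apob = QpcrMeasurement("tumor1", "APOB", tuple(
    INTERCEPT + SLOPE * np.log10(100.0) for _ in range(3)
))
call = estimate_copy_number(gstm1, apob, curve, curve)
print(f"copy call: 2 x (target/reference) = {call.continuous_estimate:.2f} "
      f"-> {call.integer_call} copy (within tolerance: {call.within_tolerance})")

# comparative delta-Ct expression: 10 cycles behind GAPDH ~ 1/1024 abundance
target = QpcrMeasurement("tumor1", "GSTM1", (32.0,))
gapdh = QpcrMeasurement("tumor1", "GAPDH", (22.0,))
rq = compute_rq(target, gapdh)
print(f"relative quantity: delta Ct {rq.delta_ct:+.1f} -> RQ x1000 = {rq.rq_x1000:.4f}")
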