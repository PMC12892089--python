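# Default SMT-parameterized risk-curve constants.
#
# A(SMT) = a_s * SMT + a_i   (quadratic coefficient, RR per degC^2)
# B(SMT) = b_s * SMT + b_i   (linear coefficient,    RR per degC)
#
# Calibrated by the package so that, over the summer-mean-temperature
# range of Texas counties (~26-31 degC), RR at the 95th-percentile
# temperature (typically 2-3 degC above OT) falls in ~1.10-1.25, with
# cooler (lower-SMT) regions getting steeper curves. These are stand-in
# defaults with the structure of the published multi-city US fits;
# replace this file to use externally fitted coefficients.
a_s: -0.0015
a_i: 0.0485
b_s: -0.005
b_i: 0.19
provenance: "heatmort package default (synthetic calibration; see docs/methods.md)"
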