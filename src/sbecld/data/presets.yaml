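# Enzyme presets for maize SBEIIa and its single-residue mutants.
# specific_activity in nmol min^-1 mg^-1 (unit-U basis, 30 degC, pH 7.4).
# x_min / x_0: minimum transferred / residual segment DP.
# min_donor_dp: donor-eligibility floor (binding-subsite count); defaults
#   to x_min + x_0 when omitted.  R456K keeps the wild-type floor of 12
#   while its fragment minima relax to 2.
# kernel: cut-position preference over the transferred length.
# unanchored: activity value is a nominal placeholder, not a measurement.
WT:
  x_min: 6
  x_0: 6
  specific_activity: 34.3
  kernel: {type: geometric, decay: 0.45}
R363K:
  x_min: 6
  x_0: 6
  specific_activity: 19.0
  kernel: {type: geometric, decay: 0.45}
R456K:
  x_min: 2
  x_0: 2
  min_donor_dp: 12
  specific_activity: 9.5
  kernel: {type: uniform}
Y352F:
  x_min: 6
  x_0: 6
  specific_activity: 0.343
  kernel: {type: geometric, decay: 0.45}
  unanchored: true
E513D:
  x_min: 6
  x_0: 6
  specific_activity: 0.343
  kernel: {type: geometric, decay: 0.45}
  unanchored: true
S349F:
  x_min: 6
  x_0: 6
  specific_activity: 0.0
  kernel: {type: geometric, decay: 0.45}
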