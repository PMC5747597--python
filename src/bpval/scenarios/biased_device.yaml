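# Stress scenario: test device reads 20 units high everywhere.
# Every selected difference lands beyond the widest band, so the
# pair-level phase fails for every variable.
n_subjects: 125
seed: 0
dropout: 0.2
session_effect_sd: 2.0
criterion_noise_sd: 1.2
test_noise_sd: 1.2
test_bias: 20.0
test_proportional_bias: 0.0
integer_rounding: true
variables:
  SBP: {mean: 127.0, sd: 16.0, trunc_low: 90.0, trunc_high: 180.0, within_subject_sd: 2.2}
  DBP: {mean: 74.0, sd: 10.0, trunc_low: 40.0, trunc_high: 130.0, within_subject_sd: 2.2}
  HR: {mean: 71.0, sd: 10.0, trunc_low: 40.0, trunc_high: 180.0, within_subject_sd: 1.5}
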