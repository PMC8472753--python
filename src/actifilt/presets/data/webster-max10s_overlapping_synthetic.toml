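# Webster scoring rule, maximum 10-s count within overlapping minutes.
# SYNTHETIC SURROGATE: the original coefficient vector could not be
# sourced.  The surrogate keeps the documented structure (a short
# two-sided weighted sum over neighbouring minutes, wake above a
# normalized threshold) with neutral uniform weights.  Numbers computed
# from this preset characterize the surrogate, not the published rule.
algorithm = "webster"
variant = "max10s_overlapping"
citation = "Webster JB et al. (1982), Sleep 5(4):389-399. Coefficients unavailable; uniform surrogate."
synthetic = true
domain = "D"
epoch_length_s = 60.0
n_past = 2
n_future = 2
weights = [0.2, 0.2, 0.2, 0.2, 0.2]
scale = 0.06
bias = 0.0
threshold = 1.0
wake_above = true
rescoring = "webster"
collapse = [
  { metric = "max", window_s = 10.0, step_s = 0.0 },
  { metric = "max", window_s = 60.0, step_s = 60.0 },
]
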