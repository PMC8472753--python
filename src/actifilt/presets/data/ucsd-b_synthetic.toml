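# UCSD scoring rule, variant "b": identical coefficient vector to
# variant "a", different multiplicative constant P (different weakening,
# same filter shape).  SYNTHETIC SURROGATE: see ucsd-a.
algorithm = "ucsd"
variant = "b"
citation = "Jean-Louis G et al. (2001). Coefficients unavailable; uniform surrogate."
synthetic = true
domain = "D"
epoch_length_s = 60.0
n_past = 2
n_future = 2
weights = [1.0, 1.0, 1.0, 1.0, 1.0]
scale = 0.004
bias = 0.0
threshold = 1.0
wake_above = true
rescoring = "none"
collapse = [
  { metric = "max", window_s = 60.0, step_s = 60.0 },
]
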