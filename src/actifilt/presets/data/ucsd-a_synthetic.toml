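# UCSD scoring rule, variant "a".  All published UCSD variants share one
# coefficient vector and differ only in the multiplicative constant P,
# i.e. they are the same filter with different weakening.
# SYNTHETIC SURROGATE: the shared coefficient vector and the published P
# constants could not be sourced; uniform weights and a nominal P stand
# in.  The shared-vector structure is preserved exactly (see ucsd-b).
algorithm = "ucsd"
variant = "a"
citation = "Jean-Louis G, Kripke DF, Mason WJ, Elliott JA, Youngstedt SD (2001). Sleep estimation from wrist movement quantified by different actigraphic modalities. Coefficients unavailable; uniform surrogate."
synthetic = true
domain = "D"
epoch_length_s = 60.0
n_past = 2
n_future = 2
weights = [1.0, 1.0, 1.0, 1.0, 1.0]
scale = 0.02
bias = 0.0
threshold = 1.0
wake_above = true
rescoring = "none"
collapse = [
  { metric = "max", window_s = 60.0, step_s = 60.0 },
]
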