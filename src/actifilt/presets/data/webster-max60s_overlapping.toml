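# Webster scoring rule, maximum count over overlapping 60-s windows.
# Transcribed via the secondary literature; the original table could not
# be consulted directly, and the spectral character of this 5-tap vector
# differs markedly from the smoother response reported for this variant,
# so the transcription is flagged as doubtful.
algorithm = "webster"
variant = "max60s_overlapping"
citation = "Webster JB, Kripke DF, Messin S, Mullaney DJ, Wyborney G (1982). An activity-based sleep monitor system for ambulatory use. Sleep 5(4):389-399. [transcription via secondary literature; doubtful]"
domain = "D"
epoch_length_s = 60.0
n_past = 2
n_future = 2
weights = [0.15, 0.15, 1.0, 0.08, 0.21]
scale = 0.025
bias = 0.0
threshold = 1.0
wake_above = true
rescoring = "webster"
collapse = [
  { metric = "max", window_s = 60.0, step_s = 0.0 },
  { metric = "max", window_s = 60.0, step_s = 60.0 },
]
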