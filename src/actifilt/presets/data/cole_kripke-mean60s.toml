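# Cole-Kripke scoring rule for mean activity per minute (counts/min).
algorithm = "cole_kripke"
variant = "mean60s"
citation = "Cole RJ, Kripke DF, Gruen W, Mullaney DJ, Gillin JC (1992). Automatic sleep/wake identification from wrist activity. Sleep 15(5):461-469."
domain = "D"
epoch_length_s = 60.0
n_past = 4
n_future = 2
weights = [106.0, 54.0, 58.0, 76.0, 230.0, 74.0, 67.0]
scale = 0.001
bias = 0.0
threshold = 1.0
wake_above = true
rescoring = "cole"
collapse = [
  { metric = "mean", window_s = 60.0, step_s = 60.0 },
]
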