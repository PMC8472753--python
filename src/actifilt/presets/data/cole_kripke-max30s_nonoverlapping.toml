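# Cole-Kripke scoring rule for data collapsed as the maximum 30-s count
# within each minute, non-overlapping.
algorithm = "cole_kripke"
variant = "max30s_nonoverlapping"
citation = "Cole RJ, Kripke DF, Gruen W, Mullaney DJ, Gillin JC (1992). Automatic sleep/wake identification from wrist activity. Sleep 15(5):461-469."
domain = "D"
epoch_length_s = 60.0
n_past = 4
n_future = 2
weights = [50.0, 30.0, 14.0, 28.0, 121.0, 8.0, 50.0]
scale = 0.0001
bias = 0.0
threshold = 1.0
wake_above = true
rescoring = "cole"
collapse = [
  { metric = "max", window_s = 30.0, step_s = 30.0 },
  { metric = "max", window_s = 60.0, step_s = 60.0 },
]
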