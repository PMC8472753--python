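# Cole-Kripke scoring rule for data collapsed as the maximum 10-s count
# within each minute, minutes non-overlapping.
# Transcription note: this coefficient set is a best-effort transcription
# whose fidelity could not be independently verified against the original
# table; treat downstream numbers for this variant with caution.
algorithm = "cole_kripke"
variant = "max10s_nonoverlapping"
citation = "Cole RJ, Kripke DF, Gruen W, Mullaney DJ, Gillin JC (1992). Automatic sleep/wake identification from wrist activity. Sleep 15(5):461-469. [unverified transcription]"
domain = "D"
epoch_length_s = 60.0
n_past = 4
n_future = 2
# published order: most-past tap first (A[n-4] ... A[n+2])
weights = [550.0, 378.0, 413.0, 699.0, 1736.0, 349.0, 568.0]
scale = 0.00001
bias = 0.0
threshold = 1.0
wake_above = true
rescoring = "cole"
collapse = [
  { metric = "max", window_s = 10.0, step_s = 10.0 },
  { metric = "max", window_s = 60.0, step_s = 60.0 },
]
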