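# Sazonov logistic scoring rule (infant actigraphy): the probability of
# sleep is a logistic function of a weighted sum of the per-epoch
# maximum counts of the current and preceding epochs.  In logit form the
# rule is a causal FIR filter plus an additive intercept; p > 0.5
# (sleep) is exactly alpha > 0, so wake is scored when the score falls
# BELOW the threshold.
# Transcription note: taken from the secondary literature, which prints
# a 5-term model (current epoch + 4 preceding); longer published forms
# of the model could not be sourced.
algorithm = "sazonov"
variant = ""
citation = "Sazonov E, Sazonova N, Schuckers S, Neuman M, CHIME Study Group (2004). Activity-based sleep-wake identification in infants. Physiol Meas 25:1291-1304. [5-term form via secondary literature]"
domain = "alpha"
epoch_length_s = 60.0
n_past = 4
n_future = 0
# most-past tap first: A[n-4] ... A[n]
weights = [-0.176, -0.140, -0.136, -0.154, -0.256]
scale = 1.0
bias = 1.727
threshold = 0.0
wake_above = false
rescoring = "none"
collapse = [
  { metric = "max", window_s = 60.0, step_s = 60.0 },
]
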