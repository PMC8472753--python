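# Scripps Clinic scoring rule: a 13-tap weighted sum over 30-s epochs
# (ten past, the current, two future), matched to the 30-s epoch grid of
# laboratory polysomnography.
algorithm = "scripps_clinic"
variant = ""
citation = "Kripke DF, Hahn EK, Grizas AP, Wadiak KH, Loving RT, Poceta JS, Shadan FF, Cronin JW, Kline LE (2010). Wrist actigraphic scoring for sleep laboratory patients: algorithm development. J Sleep Res 19(4):612-619."
domain = "D"
epoch_length_s = 30.0
n_past = 10
n_future = 2
weights = [0.0064, 0.0074, 0.0112, 0.0112, 0.0118, 0.0118, 0.0128, 0.0188, 0.0280, 0.0664, 0.0300, 0.0112, 0.0100]
scale = 0.204
bias = 0.0
threshold = 1.0
wake_above = true
rescoring = "none"
collapse = [
  { metric = "mean", window_s = 30.0, step_s = 30.0 },
]
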