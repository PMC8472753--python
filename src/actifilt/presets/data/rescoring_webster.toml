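# Webster's wake-triggered rescoring rules (the one-sided, run-length
# triggered subset; rules conditioning on wake on BOTH sides of a short
# sleep bout do not fit the run-then-span template and are not included).
name = "webster"
rules = [
  { trigger = "wake", min_run_min = 4.0,  span_min = 1.0, target = "wake" },
  { trigger = "wake", min_run_min = 10.0, span_min = 3.0, target = "wake" },
  { trigger = "wake", min_run_min = 15.0, span_min = 4.0, target = "wake" },
]
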