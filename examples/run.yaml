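# Small network demo: three pairing trials, default calibrated element.
seed: 7
dt: 0.02
markov:
  N: 20
  f: 0.2
protocol:
  n_patterns: 3
  trial_duration: 12.0
  gap: 12.0
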