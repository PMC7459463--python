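{
  "n_samples": 524288,
  "sampling_rate": 1000.0,
  "segment_length": 2048,
  "f_low": 3.0,
  "f_high": 300.0,
  "n_subbands": 5,
  "tie_tolerance": 0.05,
  "seed": 42
}
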