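{
  "segments": [
    [
      0.1,
      500.0,
      1.0
    ]
  ],
  "overall_level": 0.0001,
  "label": "reference-air"
}
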