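{
  "segments": [
    [
      0.1,
      3.0,
      0.5
    ],
    [
      3.0,
      7.535659294528742,
      0.5
    ],
    [
      7.535659294528742,
      18.928720334405796,
      1.5
    ],
    [
      18.928720334405796,
      47.546795773833416,
      1.0
    ],
    [
      47.546795773833416,
      119.43215116604924,
      0.5
    ],
    [
      119.43215116604924,
      300.0,
      0.5
    ],
    [
      300.0,
      500.0,
      0.5
    ]
  ],
  "overall_level": 0.0001,
  "label": "designed-agent"
}
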