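{
  "W_expected": [
    [
      0.0,
      -0.20893442426502054,
      -0.05125927775743726
    ],
    [
      -0.20893442426502054,
      0.0,
      0.20688130247271597
    ],
    [
      -0.05125927775743726,
      0.20688130247271597,
      0.0
    ]
  ],
  "positions": [
    [
      0.0,
      -0.371,
      -0.001
    ],
    [
      7.0,
      0.101,
      -0.471
    ],
    [
      14.0,
      -0.352,
      0.428
    ]
  ],
  "spec": {
    "geometry": 7.0,
    "n_sites": 3,
    "seed": 11,
    "site_kinds": [
      "acid",
      "base",
      "redox"
    ]
  }
}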