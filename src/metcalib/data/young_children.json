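{
  "population": "young_children",
  "non_ambulatory": {
    "form": "quadratic_fixed_intercept",
    "intercept": 0.9,
    "slope": 0.0144,
    "quad": -1.47e-05
  },
  "ambulatory": {
    "form": "linear",
    "intercept": 1.0012,
    "slope": 0.0037
  }
}
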