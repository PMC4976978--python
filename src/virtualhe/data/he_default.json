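{
  "dyes": [
    {"name": "dapi", "beta": [0.860, 1.000, 0.300]},
    {"name": "eosin", "beta": [0.050, 1.000, 0.544]}
  ],
  "k": 2.5,
  "floor": 0.0075,
  "additive_linear": {
    "backlight": [1.0, 1.0, 1.0]
  },
  "additive_nonlinear": {
    "backlight": [0.9, 1.0, 0.9],
    "transfer_exponent": 0.5
  }
}
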