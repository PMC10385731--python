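{
  "response_kind": "H",
  "variables": ["N", "PW", "HB", "TRHD", "DM", "DD18", "Eref"],
  "alpha": {
    "intercept": -2.301,
    "N": 0.014,
    "PW": 0.625,
    "HB": -0.002,
    "TRHD": 0.095,
    "DM": 1.737,
    "DD18": -0.011,
    "Eref": 0.012
  },
  "beta": {
    "intercept": 0.063,
    "N": 9.62e-07,
    "PW": -6.83e-05,
    "HB": -1.62e-06,
    "TRHD": 4.68e-05,
    "DM": 0.0,
    "DD18": -1.01e-05,
    "Eref": 2.63e-05
  }
}
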