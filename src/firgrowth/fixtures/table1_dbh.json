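{
  "response_kind": "DBH",
  "variables": ["N", "PW", "HB", "TRHD", "DM", "DD18", "Eref"],
  "alpha": {
    "intercept": -20.041,
    "N": 0.001,
    "PW": -0.096,
    "HB": -0.004,
    "TRHD": 0.155,
    "DM": -1.525,
    "DD18": 0.001,
    "Eref": 0.031
  },
  "beta": {
    "intercept": 0.039,
    "N": 5.89e-06,
    "PW": -4.11e-05,
    "HB": 4.01e-06,
    "TRHD": -6.17e-06,
    "DM": 0.0,
    "DD18": 4.79e-06,
    "Eref": -7.63e-06
  }
}
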