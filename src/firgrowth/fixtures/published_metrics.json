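{
  "description": "Published fit statistics of the Chinese-fir individual-tree growth study: the DBH covariate-ladder tables for the BP and RF models (train/test R2, MAE, RMSE; cm) and the height-model test statistics (m). Used to recompute the reported relative-improvement percentages.",
  "dbh_bp_ladder": {
    "rungs": ["T", "T+Comp", "T+Comp+Site", "T+Comp+Site+Clim"],
    "train": {
      "r2":   [0.669, 0.721, 0.809, 0.831],
      "mae":  [2.041, 1.836, 1.463, 1.342],
      "rmse": [2.626, 2.375, 1.973, 1.824]
    },
    "test": {
      "r2":   [0.638, 0.689, 0.776, 0.808],
      "mae":  [2.164, 1.962, 1.614, 1.487],
      "rmse": [2.745, 2.506, 2.141, 2.017]
    }
  },
  "dbh_rf_ladder": {
    "rungs": ["T", "T+Comp", "T+Comp+Site", "T+Comp+Site+Clim"],
    "train": {
      "r2":   [0.714, 0.782, 0.827, 0.867],
      "mae":  [1.893, 1.593, 1.368, 1.201],
      "rmse": [2.391, 2.104, 1.866, 1.573]
    },
    "test": {
      "r2":   [0.679, 0.733, 0.826, 0.849],
      "mae":  [1.997, 1.782, 1.387, 1.267],
      "rmse": [2.537, 2.281, 1.871, 1.691]
    }
  },
  "h_test": {
    "RP": {"r2": 0.683, "rmse": 2.102},
    "BP": {"r2": 0.731, "rmse": 1.857, "mae": 1.686},
    "RF": {"r2": 0.845, "rmse": 1.267, "mae": 1.153}
  }
}
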