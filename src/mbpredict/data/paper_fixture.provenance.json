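{
  "rule": "predictive",
  "params": {
    "S0": 6.9,
    "alpha": 0.79,
    "tau_o": 14.25,
    "delta_eta": 0.057,
    "tau_eta": 133.48
  },
  "n_fly": 80,
  "n_trial": 8,
  "seed": 0,
  "dt": 0.05
}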