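{
  "params": {
    "mu_max0": 0.244,
    "K_s": 11.5,
    "Z_m": 60.0,
    "K_z": 0.83,
    "family": "exponential"
  },
  "yields": {
    "Y_xs": 0.28,
    "Y_ps": 0.42,
    "Y_zs": 0.0442
  },
  "mixture": {
    "frac_glycerol": 0.56,
    "frac_acetic": 0.36,
    "frac_succinic": 0.08
  },
  "initial": {
    "t": 0.0,
    "X": 1.0,
    "S": 100.0,
    "P": 0.0,
    "Z": 0.0
  },
  "t_end": 72.0,
  "dt": 0.01,
  "threshold_fraction": 0.01,
  "seed": 0
}
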