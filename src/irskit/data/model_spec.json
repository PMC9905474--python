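{
  "coefficients": {
    "TMB": 0.273758,
    "PD-1": 0.112641,
    "PD-L1": 0.061904,
    "TOP2A": -0.077011,
    "ADAM12": -0.057991
  },
  "threshold": 0.873569,
  "gene_medians": {
    "PD-1": 30.0,
    "PD-L1": 60.0,
    "TOP2A": 200.0,
    "ADAM12": 100.0
  },
  "tmb_floor": 0.5,
  "tmb_high_cutoff": 10.0,
  "reference_rpm": {
    "HK1": 500.0,
    "HK2": 800.0,
    "HK3": 1200.0
  }
}
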