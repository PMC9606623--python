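# Four-phase comparison calibrated against a synthetic f-REBOA-arm cohort.
cohort:
  group: f_reboa
  seed: 42
  n_cycles: 10
calibrate: true
calibration_tol: 0.05
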