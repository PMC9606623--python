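# Baseline phase on the coarse default grid.
phase: baseline
numerics:
  grid_spacing: 0.00085
  max_cycles: 4
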