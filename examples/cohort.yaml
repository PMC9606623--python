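# Synthetic recording generation: p-REBOA arm, all three phases.
group: p_reboa
seed: 7
beat_noise_cv: 0.03
pressure_noise_mmhg: 1.0
flow_noise_l_min: 0.05
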