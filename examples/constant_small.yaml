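# A small constant-size model for quick demos.
name: constant_small
N_ancestral: 500
burn_in_multiplier: 4
epochs:
  - {t_start: 2000, t_end: 0, N_start: 500, growth_rate: 0.0}
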