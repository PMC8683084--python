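# Stylized piecewise-constant West-African size trajectory: no out-of-Africa
# bottleneck, roughly constant moderate size until the recent epoch, which is
# replaced by the preset builders.
name: yri_stylized
N_ancestral: 14448
burn_in_multiplier: 10
epochs:
  - {t_start: 55000, t_end: 30000, N_start: 14448, growth_rate: 0.0}
  - {t_start: 30000, t_end: 5000, N_start: 20000, growth_rate: 0.0}
  - {t_start: 5000, t_end: 50, N_start: 24000, growth_rate: 0.0}
  - {t_start: 50, t_end: 0, N_start: 24000, growth_rate: 0.0}
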