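# Stylized piecewise-constant European size trajectory spanning ~55,000
# generations: ancestral size 14,448, an out-of-Africa bottleneck, and strong
# recent growth. The most recent epoch is replaced by the preset builders.
# Substitute the published MSMC step function here (or via override_table)
# to reproduce an archived trajectory exactly.
name: ceu_stylized
N_ancestral: 14448
burn_in_multiplier: 10
epochs:
  - {t_start: 55000, t_end: 30000, N_start: 14448, growth_rate: 0.0}
  - {t_start: 30000, t_end: 5000, N_start: 20000, growth_rate: 0.0}
  - {t_start: 5000, t_end: 2000, N_start: 1861, growth_rate: 0.0}
  - {t_start: 2000, t_end: 250, N_start: 20000, growth_rate: 0.0}
  - {t_start: 250, t_end: 50, N_start: 500000, growth_rate: 0.0}
  - {t_start: 50, t_end: 0, N_start: 500000, growth_rate: 0.0}
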