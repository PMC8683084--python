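# Small end-to-end demo: synthetic sites -> forward observations -> de novo
# counts -> saturation summary. Scaled down so it runs in seconds; raise
# n_sites / n_chromosomes (and use the eur_recent10M model) for realism.
model: examples/constant_small.yaml  # path relative to the working directory
n_chromosomes: 1000
n_trios: 500
neutral: synonymous
engine: forward
stages: [synth, observations, dnms, saturation]
synthetic:
  classes:
    - annotation: synonymous
      n_sites: 200
      u: 1.0e-4
    - annotation: lof
      n_sites: 200
      u: 1.0e-4
      dfe: [[0.7, 0.0], [0.3, 0.25]]
abc:
  u: 1.0e-4
  v: 0.0
  condition: zero
  proposals: 1000
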