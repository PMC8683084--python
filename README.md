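# satcpg

Saturation analysis of highly mutable sites in large human samples:

- **`satcpg.demography`** — piecewise demographic histories (stylized European
  and West-African presets with configurable epoch tables, exponential-growth
  epochs, burn-in convention, YAML/JSON model files).
- **`satcpg.wf_forward`** — numba-accelerated forward Wright–Fisher
  simulation of a single bi-allelic site with recurrent and back mutation,
  diploid viability selection, per-generation demographic sizes, and binomial
  sampling of `n` chromosomes at present.
- **`satcpg.coalescent_lengths`** — total genealogy length under piecewise
  demography (vectorized time-rescaled Kingman coalescent, feasible at
  n = 780,000), closed-form constant-size expectations, expected mutation
  counts, and tree-length ratios between sample sizes.
- **`satcpg.saturation_stats`** — segregating fractions with exact binomial
  CIs, rescaling to a neutral class, Fisher exact tests, invariant-site
  p-values and FDRs, covariate-matched comparisons, rate-matched bins of K
  sites, de novo mutation rates with exact Poisson CIs, multi-hit counts,
  pathogenic-enrichment odds, and saturation-based genealogy-length
  estimators.
- **`satcpg.selection_inference`** — rejection ABC over priors on the
  selection coefficient conditional on the observed copy-number class
  (0, 1–10, >10 copies), Bayes odds of strong selection, deterministic
  mutation–selection-balance expectations, and DFE mixture arithmetic.
- **`satcpg.synthetic_data`** — synthetic site tables with hidden
  ground-truth selection coefficients kept in a separate file, forward or
  genealogy-based observation engines, and Poisson de novo counts.
- **`satcpg.pipeline_cli`** — the `satcpg` command-line interface.

## CLI

```sh
# forward simulation of one site, 100 replicates
satcpg simulate --u 1.2e-7 --v 5e-9 --s 0 --model eur_recent10M \
    --n 780000 --reps 100 --seed 1 --out sims.tsv

# mean total genealogy length of a 780K-chromosome sample
satcpg treelength --model eur_recent10M --n 780000 --reps 20 --seed 1

# synthetic site table + observations + saturation summary, one pipeline
satcpg run --config examples/demo_pipeline.yaml --seed 1 --outdir out/

# ABC posterior of hs for an invariant site
satcpg abc --u 1.2e-7 --v 5e-9 --model eur_recent10M --n 780000 \
    --condition zero --proposals 100000 --seed 1 --out posterior.tsv
```

Demographic models are preset names (`eur_recent10M`, `eur_recent100M`,
`eur_expgrowth`, `yri_recent10M`, `constant`) or YAML/JSON files with keys
`{name, N_ancestral, burn_in_multiplier, epochs: [{t_start, t_end, N_start,
growth_rate}]}`. The packaged European/West-African epoch tables are
stylized; to reproduce an archived trajectory exactly, supply the published
epoch sizes via a model file or `override_table`.

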