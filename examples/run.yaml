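# Demo configuration for `methepi run --config examples/run.yaml --outdir out/`
# Small genome so the full pipeline finishes in seconds.
seed: 1
synthetic:
  genome_length: 10000
  coverage_mean: 20
phenotypes:
  n_fish_per_genotype: 30
dmr:
  group_a: dnmt1
  group_b: wt
interaction:
  alpha: 0.05
  error_mode: standard
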