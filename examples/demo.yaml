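# End-to-end demonstration config. Only the seed is mandatory; anything
# omitted falls back to the defaults in tractmix.pipeline.DEFAULT_CONFIG
# (4 panels at drift F=0.1, 8 one-Morgan autosomes + X, 60 genomes).
seed: 42
cohort:
  n_genomes: 60
  proportions: [0.45, 0.25, 0.2, 0.1]
  # female-biased founding for the first two components: the X chromosome
  # carries more of them than the autosomes
  proportions_x: [0.55, 0.3, 0.1, 0.05]
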