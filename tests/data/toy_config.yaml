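# Small end-to-end pipeline configuration used for regression testing.
seed: 73
orientation:
  denominator: NZO
  numerator: C3H
simulate:
  n_genes: 60
  exon_count_range: [3, 8]
  frac_de: 0.15
  frac_as: 0.15
arh:
  resamples: 500
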