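# Full pipeline run on the packaged synthetic POLG-like conditions:
#   dualorf run --config examples/polg_like.yaml
seed: 7
out_dir: dualorf_out
stages: [align, survey, synscan, start, ribo, variants]
alignment:
  n_species: 12
  branch_length: 0.4
  orf_len: 300
  overlap: [60, 160]
  mode: dual_constrained
synscan:
  window_codons: 25
  threshold: 0.05
ribo:
  n_reads: 50000
  flank: 60
  init_fraction: {ORF-Z: 0.3, ORF-Y: 0.6, main: 1.0}
variants:
  n: 15
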