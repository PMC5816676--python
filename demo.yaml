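seed: 11
sim:
  n_snps: 1500
  chrom_lengths: {chr1: 120000000, chr2: 120000000}
  n_lines: 150
  mean_depth: 1.0
  error_rate: 0.01
  qtls:
    - {chrom: chr2, pos_bp: 30000000, add: 1.4, dom: 1.4}
  var_line_poly: 1.0
  var_line_loc: 0.2
  var_line_year: 0.2
  var_residual: 1.0
  intercept: 10.0
qc:
  min_genotyped: 500
scan:
  n_permutations: 100
  n_cofactors: 2
  location: loc1
  year: year1
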