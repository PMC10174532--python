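# Desk-scale demonstration run: one planted QTL on chr04.
seed: 7
profile: desk
reporter: ODC
out_dir: runs/demo
simulation:
  n_segregants: 50000
  fraction: 0.02
  n_cells: 20000
  coverage: 21.0
  architecture:
    noise_sd: 1.0
    loci:
      - {chrom: chr04, pos: 35000, effect: 0.5}
mapping:
  bin_bp: 100
  bp_per_cM: 2200.0
  n_eff: 1000.0
  kernel_sd_bp: 10000.0
  lod_threshold: 4.5
  span_bp: 50000
overlap:
  max_dist: 100000
  min_qtls: 7
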