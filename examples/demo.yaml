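# Demo run: small synthetic dual-genome experiment (completes in seconds).
#   spikecal run --config examples/demo.yaml --outdir demo_out
sim:
  n_target_genes: 200
  n_spike_genes: 60
  n_replicates_per_condition: 3
  spike_cell_fraction: 0.25
  mixing_cv: 0.05
  frac_shifted: 0.3
  shift_log2fc: 1.0
  dispersion: 0.05
  mean_depth: 500000.0
  seed: 42
  baseline_sigma: 1.5
  frac_low: 0.2
  low_scale: 0.05
  depth_cv: 0.1
  input_depth: null
track_shape:
  contig: chrT
  contig_bp: 610000
  bin_bp: 10
  gene_length_bp: 2000
  gap_bp: 1000
  promoter_bp: 300
  promoter_density: 10.0
  body_density: 2.0
  background_density: 0.5
  noise_cv: 0.1
padj_threshold: 0.05
fold_threshold: 1.4
correlation_gate: 0.95
promoter_window: 1000
pausing_promoter: [-30, 300]
flank_bp: 500
profile_bin_bp: 10
pseudocount: 1.0
seed: 42
log_level: INFO
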