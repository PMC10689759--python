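# Compact cohort for a fast first run (~30 s).
# Run with:  cfsig all --config examples/quick_config.yaml --outdir runs/quick
seed: 20
reference:
  n_chrom: 2
  chrom_length_bp: 2000000
  cpg_cluster_rate: 3.0e-4
cohort:
  n_healthy: 56
  n_per_cancer: 16
  n_tumor_tissue: 8
  n_normal_tissue: 8
  mean_depth: 30.0
  n_fragments: 30000
generator:
  n_tissue_markers: 20
  n_cancer_markers: 20
bins:
  width: 10000
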