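# Full demonstration cohort: ~200 samples, ~20,000 CpG blocks,
# 2,000 genomic bins, 100,000 fragments per sample.
# Run with:  cfsig all --config examples/demo_config.yaml --outdir runs/demo
seed: 7
reference:
  n_chrom: 4
  chrom_length_bp: 5000000
  cpg_cluster_rate: 1.7e-3   # ~20,000 CpG blocks over the toy genome
cohort:
  n_healthy: 64
  n_per_cancer: 24
  n_tumor_tissue: 6
  n_normal_tissue: 6
  mean_depth: 30.0
  n_fragments: 100000
bins:
  width: 10000        # 2,000 bins over the 20-Mb toy genome
fragmentomics:
  min_bin_count: 25   # scaled to the ~50 fragments per 10-kb bin of this demo
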