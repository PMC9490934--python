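# Full-pipeline configuration for `lncnet run-all --config ...`.
# Either keep the synthetic block (planted-module simulation) or replace
# it with expression_path / annotation_path / samples_path (TSV), plus
# optional ppi_path (edge list TSV) and gmt_path (gene sets).
synthetic:
  n_lncrna: 800
  n_mrna: 1200
  n_modules: 5
  stages: [0, 1, 7, 14]
  replicates_per_stage: 3
  membership_range: [0.7, 0.95]
  noise_sd: 1.0
  background_fraction: 0.85

seed: 1
out_dir: lncnet_out

# differential expression
p_cut: 0.05
fc_cut: 2.0

# network
beta: auto          # or an integer, e.g. 18
min_module_size: 20

# hub funnel
gs_cut: 0.5
mm_cut: 0.9
k_mrna: 20
k_lncrna: 10
r_threshold: 0.9
p_threshold: 0.05

# enrichment
min_overlap: 5
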