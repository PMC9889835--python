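# Full-pipeline configuration for `strawcue run-all examples/run_all_config.yaml`.
# Exactly one input source is allowed: the `synthetic:` block below, or an
# `inputs:` block with paths to measurement tables (isotope_samples,
# bacterial_counts, bacterial_taxonomy, fungal_counts, fungal_taxonomy,
# sample_metadata, gene_abundances, optionally oa_composition).
seed: 1
output_dir: strawcue_out
synthetic:
  design: {}            # defaults: Ctrl/LM/MM/CM x days 7,28; delta_straw 99 permil
  noise_sd_delta: 1.0   # permil, Gaussian noise on delta values
  noise_cv_pools: 0.05  # log-normal CV on pool sizes
stages:
  isotope: true
  community: true
  network: true
  importance: true
  composition: true
params:
  isotope:
    kec: 0.45
    ci_method: t
  community:
    n_permutations: 999
  network:
    method: spearman
    r_threshold: 0.6
    p_threshold: 0.01
    module_algo: greedy
  importance:
    n_trees: 500
    n_null: 100
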