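# Full discovery/validation workflow configuration for `tnbckit run-all`.
# Paths are resolved relative to this file.

matrices:            # one log2 genes x samples TSV (or GCT) per dataset
  - dsA_matrix.tsv
  - dsB_matrix.tsv
  - dsC_matrix.tsv
  - dsD_matrix.tsv
meta:                # sample_id-keyed TSVs: dataset_id, batch, platform,
  - dsA_meta.tsv     # preservation, survival_time, event
  - dsB_meta.tsv
  - dsC_meta.tsv
  - dsD_meta.tsv

seed: 1              # mandatory master seed; the whole run is reproducible
output_dir: run_out

scheme: per_platform # or: pooled
top_fraction: 0.10   # per-gene-SD feature selection, per arm; union shared
k_min: 2
k_max: 10
n_iter: 1000         # consensus resampling iterations
subsample_fraction: 0.8
delta_threshold: 0.05
# force_k: 6         # override the CDF elbow rule

de_alpha: 0.05
de_fc_min: 1.5

survival: true       # needs survival_time + event columns in the metadata

signatures:          # optional centroid signatures to assign per arm
  burstein80:
    path: burstein_centroids.tsv
    scaling: robust  # none | standard | robust
    min_r: 0.1
    er_filter: within_sample
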