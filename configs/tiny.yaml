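# Small end-to-end configuration: 4 ground-truth clusters, reduced gene
# counts and a bounded cluster-number scan.  Method settings (stability
# selection, thresholds) are the standard defaults.
mode: two-season-averaged
seed: 0
n_clusters: 4
genes_per_cluster: 15
n_low_cv_genes: 10
n_low_mean_genes: 10
n_background_genes: 120
k_max: 8
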