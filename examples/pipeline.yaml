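# Full-pipeline configuration for `reportmix run`.
# Omit input_csv to analyse the packaged synthetic dataset instead.
seed: 1
input_csv: null
scenario: default
trials_per_cell: 300
experiments: [set_size, cue_delay]
n_list: [1, 2, 3, 4, 5]
trend_n: 2
alpha: 0.05
n_starts: 20
fix_means_at_zero: true
out_dir: reportmix_out
make_figures: true
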