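# Example configuration for `ccs-bimodal run --config pipeline.toml`.
# Paths are relative to where you invoke the command.
input = "data.tsv"
output_dir = "run"
seed = 1
charge = 3
min_length = 15
proteases = ["trypsin", "lysn"]
n_basic_sites = 3
separator_strategy = "refit"
min_bin_count = 8
map_features = [
    ["length", "min_internal_site_distance"],
    ["length", "proline_count"],
]

[penalties]
pos_deriv = 1.0
pos_ridge = 0.001
len_deriv = 1.0
len_ridge = 0.001
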