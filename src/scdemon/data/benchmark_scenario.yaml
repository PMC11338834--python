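# Fixed benchmark scenario for planted-module recovery: 5,000 cells,
# 2,000 genes, 5 modules of 60 genes, 3 batches, seed 0.
n_cells: 5000
n_genes: 2000
n_modules: 5
module_size: 60
n_batches: 3
cell_type_props: [0.5, 0.3, 0.2]
loading: 2.0
active_mean: 1.0
inactive_mean: 0.0
activity_sd: 1.0
nb_dispersion: 10.0
batch_sd: 0.15
libsize_sd: 0.3
sparsity_range: [0.02, 0.95]
module_sparsity_range: [0.10, 0.90]
seed: 0
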