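J: 21000
L: 1000
base_seed: 1
generations: 100.0
k_max: 20
m: 0.08
metacommunity_size: 150000
model: lv_filter
n_nulls: 100
n_replicates: 100
params:
  filter: quadratic
theta: 50.0
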