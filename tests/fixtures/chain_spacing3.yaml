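width: 21
height: 11
n_primates: 20
n_trees: 5
n_sources: 1
dynamic_trees: false
n_steps: 5000
tree_lifespan: 10000
regrow_radius: 10
search_radius: 2
interaction_radius: 1
usable_threshold: 2000.0
baseline_break_prob: 0.0
fragility_levels:
- 0
initial_mass_mean: 4000.0
initial_mass_sd: 0.0
fragment_distribution:
  kind: lognormal_mixture
  p_large: 0.1
  small_median: 6.0
  small_sigma: 0.8
  large_median: 100.0
  large_sigma: 0.7
seed: 0
torus: false
record_every: null
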