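width: 40
height: 40
n_primates: 10
n_trees: 8
n_sources: 4
dynamic_trees: false
n_steps: 1000
tree_lifespan: 10000
regrow_radius: 10
search_radius: 2
interaction_radius: 1
usable_threshold: 2000.0
baseline_break_prob: 0.25
fragility_levels:
- 0
initial_mass_mean: 6000.0
initial_mass_sd: 2000.0
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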