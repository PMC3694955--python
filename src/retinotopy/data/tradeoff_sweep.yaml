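# Countergradient-strength x compensation-decay trade-off sweep.
# Both countergradient heights are scaled relative to the fig4 baseline
# (scale 1 = half the gradient height, so scale 2 = exactly matched
# gradients and countergradients).  The map error per cell is the
# goodness-of-fit g of the wild-type map against a synthetic identity
# target map, averaged over seeds.  The decay minimising the error should
# not decrease as the countergradients strengthen: poorly matched
# countergradients need strong compensation, matched ones need none.
name: tradeoff_sweep
description: >
  Desk-scale sweep over countergradient scale x compensation decay on
  wild-type maps; reports per-cell mean map error and the best decay per
  scale.
base_scenario: fig4_weak_counter
scales: [0.0, 0.5, 1.0, 2.0]
mus: [2.0, 8.0, 32.0]
n_seeds: 3
target:
  n_points: 100
  noise_sd: 0.05
sim:
  n_rgc: 240
  n_sc: 240
  terminals_per_axon: 16
  n_steps: 4000000
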