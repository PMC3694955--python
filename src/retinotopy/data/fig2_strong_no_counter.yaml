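# Gradients with strong compensation and no countergradients.
# Heights/rates are package conventions (the source legends' numeric values
# are not transcribed here); countergradient heights of exactly 0 and the
# zero decay (strong compensation) define the regime.
name: fig2_strong_no_counter
description: >
  Forward-signalling gradients only; the accumulating (non-decaying)
  compensation spreads terminals into an ordered, uniform-density map.
gradients:
  retinal_epha:    {height: 1.0, rate: 4.0}   # convention
  retinal_ephrina: {height: 0.0, rate: 4.0}   # regime: countergradient off
  sc_ephrina:      {height: 1.0, rate: 4.0}   # convention
  sc_epha:         {height: 0.0, rate: 4.0}   # regime: countergradient off
genotype: {epha3_knockin: none, epha4_dosage: 2, rgc_survival_fraction: 1.0}
retinal_epha_source: gradient
sim:
  n_rgc: 240
  n_sc: 240
  terminals_per_axon: 16
  mu: 0.0          # regime: strong compensation
  n_steps: 40000000
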