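# Weak countergradients added to gradients with weak compensation.
# Countergradients at half the gradient heights is transcribed from the
# source description ("half the height of the gradients"); the absolute
# heights/rates and mu are package conventions.
name: fig4_weak_counter
description: >
  Countergradients at half the gradient height act with weak compensation
  to pull the map back toward the identity; rostral displacements shrink
  relative to fig3.
gradients:
  retinal_epha:    {height: 1.0, rate: 4.0}
  retinal_ephrina: {height: 0.5, rate: 4.0}   # transcription: half-height
  sc_ephrina:      {height: 1.0, rate: 4.0}
  sc_epha:         {height: 0.5, rate: 4.0}   # transcription: half-height
genotype: {epha3_knockin: none, epha4_dosage: 2, rgc_survival_fraction: 1.0}
retinal_epha_source: gradient
sim:
  n_rgc: 240
  n_sc: 240
  terminals_per_axon: 16
  mu: 8.0
  n_steps: 10000000
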