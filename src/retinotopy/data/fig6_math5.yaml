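# Math5 knock-out: 5% of the wild-type RGC complement (transcription),
# evenly spread across the retina; all other parameters identical to fig4.
# With few axons there is little density pressure, so the map clumps at
# the rostrally favoured end and does not cover the SC.
name: fig6_math5
description: >
  5% of RGCs with fig4 gradients and weak compensation; the map occupies
  only a rostral fraction of the SC.
gradients:
  retinal_epha:    {height: 1.0, rate: 4.0}
  retinal_ephrina: {height: 0.5, rate: 4.0}
  sc_ephrina:      {height: 1.0, rate: 4.0}
  sc_epha:         {height: 0.5, rate: 4.0}
genotype: {epha3_knockin: none, epha4_dosage: 2, rgc_survival_fraction: 0.05}
retinal_epha_source: gradient
sim:
  n_rgc: 240
  n_sc: 240
  terminals_per_axon: 16
  mu: 8.0
  n_steps: 1000000
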