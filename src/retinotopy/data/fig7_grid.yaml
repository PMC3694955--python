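# Genotype grid: wild type, six EphA3-knock-in x EphA4-knock-out
# combinations, and the Math5 knock-out, each run under two regimes:
#   A: the fig5 countergradients with stronger compensation (smaller decay)
#   B: retinal countergradients four times as strong and tenfold larger
#      decay (weaker compensation)
# The x4 and x10 ratios are transcriptions; the absolute regime-A decay is
# a package convention.
name: fig7_grid
description: >
  Eight genotypes under two countergradient/compensation regimes; maps and
  double-map separations are reported per genotype.
gradients:
  retinal_epha:    {height: 1.0, rate: 4.0}   # unused: measured table
  retinal_ephrina: {height: 0.5, rate: 4.0}
  sc_ephrina:      {height: 1.0, rate: 4.0}
  sc_epha:         {height: 0.5, rate: 4.0}
retinal_epha_source: measured
regimes:
  A: {mu: 2.0, retinal_ephrina_scale: 1.0}
  B: {mu: 20.0, retinal_ephrina_scale: 4.0}   # transcription: x4, x10 ratios
genotypes:
  wildtype:        {epha3_knockin: none, epha4_dosage: 2, rgc_survival_fraction: 1.0}
  ki_het_epha4_2:  {epha3_knockin: het,  epha4_dosage: 2, rgc_survival_fraction: 1.0}
  ki_het_epha4_1:  {epha3_knockin: het,  epha4_dosage: 1, rgc_survival_fraction: 1.0}
  ki_het_epha4_0:  {epha3_knockin: het,  epha4_dosage: 0, rgc_survival_fraction: 1.0}
  ki_hom_epha4_2:  {epha3_knockin: hom,  epha4_dosage: 2, rgc_survival_fraction: 1.0}
  ki_hom_epha4_1:  {epha3_knockin: hom,  epha4_dosage: 1, rgc_survival_fraction: 1.0}
  ki_hom_epha4_0:  {epha3_knockin: hom,  epha4_dosage: 0, rgc_survival_fraction: 1.0}
  math5:           {epha3_knockin: none, epha4_dosage: 2, rgc_survival_fraction: 0.05}
sim:
  n_rgc: 240
  n_sc: 240
  terminals_per_axon: 16
  n_steps: 6000000
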