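# Homozygous EphA3 knock-in: extra EphA in every second RGC produces a
# doubled map, the knock-in map lying rostral.
# The retinal EphA profile is the measured in-situ quantification
# (transcription: graded 0.26*exp(2.3*(1-x)), EphA4 0.525/allele, EphA3
# increment 1.86); SC gradients and countergradients as in fig4.
name: fig5_hom_knockin
description: >
  Measured retinal EphA gradients plus a homozygous EphA3 increment in
  alternating RGCs; two interleaved maps develop.
gradients:
  retinal_epha:    {height: 1.0, rate: 4.0}   # unused: measured table below
  retinal_ephrina: {height: 0.5, rate: 4.0}
  sc_ephrina:      {height: 1.0, rate: 4.0}
  sc_epha:         {height: 0.5, rate: 4.0}
genotype: {epha3_knockin: hom, epha4_dosage: 2, rgc_survival_fraction: 1.0}
retinal_epha_source: measured   # transcription: in-situ quantification
sim:
  n_rgc: 240
  n_sc: 240
  terminals_per_axon: 16
  mu: 8.0
  n_steps: 10000000
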