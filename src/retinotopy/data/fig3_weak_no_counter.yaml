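# Weak compensation with gradients but no countergradients: the decaying
# compensation cannot overcome the universal rostral bias, so terminals are
# displaced rostrally and caudal density is depleted.
# mu is a package convention chosen so the steady-state compensation range
# (density/mu) is comparable to, but does not dominate, the molecular
# inhibition range (see docs/methods.md).
name: fig3_weak_no_counter
description: >
  Same gradients as fig2 but decaying compensation; the final map is
  shifted rostrally from the identity.
gradients:
  retinal_epha:    {height: 1.0, rate: 4.0}
  retinal_ephrina: {height: 0.0, rate: 4.0}
  sc_ephrina:      {height: 1.0, rate: 4.0}
  sc_epha:         {height: 0.0, rate: 4.0}
genotype: {epha3_knockin: none, epha4_dosage: 2, rgc_survival_fraction: 1.0}
retinal_epha_source: gradient
sim:
  n_rgc: 240
  n_sc: 240
  terminals_per_axon: 16
  mu: 8.0          # regime: weak compensation (convention)
  n_steps: 10000000
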