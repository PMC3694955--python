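# Methods

## Model

The package implements a generalised Gierer-style model of the
one-dimensional retinocollicular map: retinal ganglion cells (RGCs) at
positions `x ∈ [0,1]` along the nasotemporal axis (temporal pole at 0)
project to cells at positions `y ∈ [0,1]` along the rostrocaudal axis of
the superior colliculus (SC, rostral pole at 0).

### Gradients and countergradients

Four exponential concentration profiles, each with a height and a
decay-or-rise constant (eight parameters in total):

| profile | form | orientation |
|---|---|---|
| retinal EphA | `α_E e^{−a_E x}` | high temporal |
| retinal ephrin-A | `α_e e^{+a_e x}` | high nasal |
| SC ephrin-A | `β_e e^{+b_e y}` | high caudal |
| SC EphA | `β_E e^{−b_E y}` | high rostral |

Retinal EphA and SC ephrin-A form the forward-signalling *gradient*
system; retinal ephrin-A and SC EphA form the reverse-signalling
*countergradient* system. Both pathways are repulsive.

### Branching inhibition

A terminal of the axon from `x` experiences, at SC position `y`, the
molecular branching inhibition

    I(x, y) = [EphA]_ret(x) · [ephrinA]_SC(y) + [ephrinA]_ret(x) · [EphA]_SC(y)

— plain products with unit coupling constants; saturating variants are
deliberately out of scope. The total branching inhibition adds the
density-compensation level `c(y)` (below): `T(x, y) = I(x, y) + c(y)`.

### Closed-form optimal map

For pure exponentials with positive countergradient heights and SC
rates, `∂I/∂y = 0` gives the affine optimal map

    y(x) = [ (a_E + a_e) x + ln( b_E α_e β_E / (b_e α_E β_e) ) ] / (b_E + b_e)

Matched heights and rates give the identity `y(x) = x`. The closed form
is returned unclamped so callers can distinguish "optimum outside the
SC" from "optimum at the boundary"; `clamp_to_sc` projects onto [0,1].
A brute-force grid argmin (`optimal_position_bruteforce`, ties broken
toward the rostral pole) serves as the independent oracle; tests require
agreement within one grid spacing over random parameter draws. Note the
direction of height perturbations: doubling the retinal EphA height
shifts the optimum *rostrally* by `ln 2 / (b_E + b_e)` — more axonal
EphA means more forward repulsion from the caudally rising ephrin-A.

### Density compensation

Each SC cell `j` carries a compensation level `c_j` fed by the terminal
density `ρ_j` (column sums of the counts matrix) and decaying at rate
`μ`. After every move attempt:

    c_j ← c_j + ε (ρ_j − μ c_j)      for all j

with `ε = 1/(number of axons × terminals per axon)`, the scaling that
keeps map development at the same apparent rate across system sizes
(after a Math5-style reduction ε is recomputed from the surviving axon
count). `μ = 0` is *strong* compensation — `c` can only accumulate,
an unbounded memory of past densities. `μ > 0` is *weak* compensation,
with fixed point `c_j = ρ_j / μ`, so the steady-state compensation range
shrinks as `μ` grows.

### Discrete dynamics

240 RGCs × 16 terminals on 240 SC cells by default. Terminals start on
uniform-random SC cells and compensation starts at zero. Each step: one
terminal is chosen uniformly at random among all terminals; if the total
inhibition for its axon is strictly lower in a neighbouring cell, it
moves to the lower neighbour (boundary cells have one neighbour; an
exact tie between two strictly lower neighbours is broken by a fair
coin); then the global compensation update runs. The update schedule
(one selection, one move attempt, one global compensation update) is a
fixed, documented choice of this package — endpoint behaviour, not the
transient, is the tested surface. Runs are bit-reproducible given
(config, gradients, genotype, seed); each step consumes exactly two
uniforms (terminal choice, tie-break) so the two runners below share the
random stream.

Two runners produce the same trajectories: a naive reference that
applies the update to every cell each step, and the default fast path
that updates each cell lazily. Laziness is exact, not approximate:
between the moves that touch a cell its density is constant, so the
elapsed updates have a closed form (`c += ε ρ Δt` for μ = 0, geometric
relaxation toward `ρ/μ` otherwise). Equivalence is tested; the two paths
agree to floating-point round-off in the compensation and, on all tested
configurations, give identical move sequences.

### Genotypes

* **EphA3 knock-in** — the retinal EphA of every second RGC is raised by
  a constant increment (half of it in heterozygotes). The mosaic is a
  deterministic alternation, an idealisation of the biological ~40%
  random mosaic, so the knock-in fraction is exactly 50%.
* **EphA4 dosage** — EphA4 is uniform along the nasotemporal axis; each
  allele adds a constant to every RGC (0, 1 or 2 copies).
* **Math5 knock-out** — `round(0.05 × n)` RGCs survive, spread evenly
  across the retina by a systematic subsample (one RGC from the centre
  of each of k equal blocks); a seeded uniform-random mode is available.

For knock-in genotypes the quantitative retinal EphA profile follows the
published in-situ hybridisation quantification: graded part
`0.26 e^{2.3 (1−x)}`, EphA4 contribution 0.525 per allele (1.05 in wild
type), EphA3 increment 1.86 (homozygous) / 0.93 (het), in relative
signal units.

## Map analysis

The simulated map is summarised per RGC by the count-weighted mean SC
position of its 16 terminals. Experimental-style maps — point sets
`(x, y)`, optionally labelled by population — are smoothed by a
Gaussian-kernel local-linear regression. The bandwidth is selected by
the Kullback-Leibler-motivated AIC criterion (statsmodels `KernelReg`,
`bw="aic"`); least-squares cross-validation is available as an
alternative but a Monte-Carlo calibration check showed its well-known
instability (bandwidths varying over five orders of magnitude across
draws of the same map, deflating the nominal coverage of the standard
errors from 95% to 89%). Pointwise standard errors of the fitted mean
come from the smoother's hat rows in heteroscedasticity-consistent
sandwich form, `se(x₀)² = Σᵢ lᵢ(x₀)² ε̂ᵢ²/(1−hᵢᵢ)²`, with HC3 leverage
correction; local variance estimation matters because the synthetic
maps' clamping at the axis boundaries makes the noise heteroscedastic.

The goodness-of-fit between a simulated map and a fitted experimental
curve is

    g = (1/N) Σ_i [ (ȳ_i − ŷ(x_i))² / σ̂(x_i)² ]

an average, so it is invariant to RGC reordering and duplication, and
zero iff the simulated means lie exactly on the curve. Standard errors
below a floor (default 10⁻³ of the SC axis) are clamped before
weighting. Only RGCs inside the convex hull of the experimental x values
are scored — the regression is never extrapolated; whether the original
analyses clamped or excluded such points is unstated, and exclusion is
the conservative choice. For double maps g is computed per population
against its own curve and the two values are averaged; a
single-population map reduces to the plain statistic.

Because g weights deviations by the fit's own standard error, a
simulated map that agrees with the data-generating curve still scores
g ≈ 1 (the fit deviates from truth by about one standard error); the
pipeline-closure test therefore uses g < 3 as its bound, with
genuinely wrong maps scoring orders of magnitude higher.

## Synthetic experimental maps

`synth_experimental_map` stands in for digitised anatomical maps: x
uniform on [0,1], `y = truth(x) + N(0, sd)` clamped to [0,1], with an
optional constant rostral offset applied to alternate points to emulate
the doubled knock-in maps. It emulates the *already converted* map form
only — in particular the cumulative-dye-intensity profile of the Math5
data is assumed to have been converted to a map upstream. It does not
emulate ectopic termination zones, per-animal sparsity of injections, or
axis-registration error between animals; tests passing against it show
that the pipeline recovers known truths from idealised scatter, not that
the model fits real anatomy.

## Parameter choices

Numeric values printed in the source figure legends are not available to
this implementation; the package's scenario files therefore mix
transcriptions (marked in the YAML comments) with package conventions:

* Gradient heights 1, rates 4 (retinal EphA, SC ephrin-A). The rate
  sets the molecular signal-to-noise of the dynamics: with much shallower
  gradients the per-cell molecular differences drown in the shot noise
  of the discrete compensation field and the strong-compensation regime
  orders impractically slowly.
* Countergradients at half the gradient heights (transcribed ratio),
  same rates.
* Weak-compensation decay μ = 8. The steady-state compensation range is
  then `Δρ/8`, comparable to but smaller than the molecular inhibition
  differences, which realises the defining phenotype of the weak regime:
  a visible rostral displacement with depleted caudal density that
  countergradients partially correct. The genotype-grid scenario uses
  μ = 2 with the baseline countergradients and μ = 20 with four-fold
  retinal countergradients (the transcribed ×4 / ×10 ratios).
* Step counts per scenario were set from convergence diagnostics (the
  accepted-move rate and the plateau of the order metrics): 4 × 10⁷ for
  strong compensation — which is diffusion-limited, ordering time
  growing roughly with the square of the SC size — and 10⁷ for the weak
  regimes, 10⁶ for Math5 (fewer terminals, faster churn), 4 × 10⁶ per
  sweep cell. Stopping is always an explicit step count; the convergence
  diagnostic is reported but never stops a run implicitly.

## Trade-off sweep

The sweep quantifies the hypothesis that countergradient matching and
compensation strength trade off in producing good wild-type maps. Both
countergradient heights are scaled by {0, ½, 1, 2} relative to the
half-height baseline — so scale 2 is exactly matched gradients — against
decay values {2, 8, 32}, three seeds per cell. Each run's map error is
the goodness-of-fit g of the wild-type map against a synthetic identity
target map. Scaling both countergradients (rather than the retinal one
alone) makes the mismatch, and with it the compensation demand, vanish
at the top of the scale range, which is what lets the optimum move: below
matching, stronger compensation (smaller decay) always improves the
wild-type map; at matching, compensation is dispensable and its density
noise is a pure cost, so the best decay jumps to the largest value. The
reported summary is the error-minimising decay per scale, which is
non-decreasing in the countergradient scale.

## Known limitations

* 1D geometry; no activity or activity-dependent plasticity, no
  fibre–fibre interactions, no marker induction, no receptor/ligand
  saturation — the model explains ordering, displacement, doubling and
  coverage, not ectopic termination zones.
* The strong-compensation regime equilibrates diffusively, so its final
  rank correlation at full scale (~0.98) sits below the matched
  chemoaffinity limit (~1.0) at any affordable step count, and its
  density retains fluctuations of a few terminals per cell (CV ≈ 0.24,
  just below that of the random initial allocation).
* Scored comparisons against published experimental fit values require
  the digitised maps from the knock-in literature and are out of scope;
  the property suite on synthetic maps replaces them.
* The DiI-injection helper merely selects RGCs within a retinal radius
  for qualitative inspection of apparent map collapse; no statistic is
  defined on it.
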