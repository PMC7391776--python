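# Methods

## The model

`microverse` simulates a community of digital microbes on a toroidal 2D
lattice (default 45×45, one cell per site).  The world contains a single
externally supplied resource metabolite R; everything else a cell needs
must be made from it through an artificial biochemistry of 9 metabolites
and 59 reactions (43 enzymatic conversions, 8 importers, 8 exporters — the
energy carrier E cannot be transported).  Two *building blocks* B1 and B2
are non-substitutable inputs to biomass production; E is the currency that
powers active transport.  Fitness is not predefined: whether a mutation
helps depends on the cell's genome, its local environment and the
surrounding community.

Each cell carries a linear genome of enzyme and transporter genes with
evolvable kinetic parameters (promoter strength, Michaelis constants,
maximal rate, transport direction — each confined to [0.01, 8]).  Within a
time step the cell's physiology evolves by ODEs:

* **Transport** — v = v_max·[T]·([S]/([S]+K_S))·([E]/([E]+K_E)); the
  substrate concentration is external for importers and internal for
  exporters, and one unit of E is consumed per unit moved (the energy
  stoichiometry of transport is not specified beyond "consumes energy";
  1:1 is the package's choice, exposed as `transport_energy_cost`).
* **Catalysis** — v = v_max·[ℰ]·∏_R [R] / ∏_R ([R]+K), with a single
  Michaelis constant per gene shared by its reactants.  Each distinct
  reactant enters the rate law once; stoichiometric coefficients apply to
  consumption and production fluxes.  An optional config switch
  (`stoichiometric_rate_law`) instead raises reactant concentrations to
  their stoichiometric power in the numerator.
* **Production** — the biomass budget B is produced at
  [B1][B2]/(1+|B1−B2|), maximal when the blocks are balanced, consuming
  both blocks 1:1 with the budget made.
* **Budget scaling** — spending (growth, expression) is multiplied by
  B/(B+B_pop), where B_pop is an exponential moving average (horizon 100
  steps) of the population's mean production.  This keeps selection
  pressure roughly constant as communities get more productive.
* **Growth and expression** — volume follows logistic growth toward
  Vol_max scaled by the budget factor, minus a small shrink rate; protein
  expression adds Pr·B_scaling per gene; both charge the budget.
* **Degradation and dilution** — every molecule degrades at its own rate
  and is diluted by volume change.  Dilution uses the signed volume
  derivative, so per-molecule *amounts* (concentration × volume) change
  only through real fluxes; this makes the conservation audits exact.

Death is stochastic: the per-step hazard starts at the intrinsic rate
r = 0.03 and saturates toward 1 with the cumulative toxic effect
e_tox = Σ_m ∫ max(0, ([m]−tox_m)/tox_m) dt, accumulated over the cell's
lifetime (survivors keep it; offspring start at zero).  Cells whose volume
falls below a starvation threshold are marked for death.  Dead cells lyse,
returning their internal metabolites to the local pool.

Reproduction is a per-empty-site lottery among Moore-neighbour cells above
the division volume, weighted by each competitor's instantaneous
production value, plus a "no reproduction" pseudo-entrant whose weight is
the running B_pop average.  The winner halves its volume (concentrations
unchanged) and the offspring genome is copied through the mutation
operators: stretch duplication/deletion/inversion/translocation (each
0.001 per replication, geometric stretch length with parameter 0.3), and
per-gene point mutations (0.02) that modify one evolvable parameter
(multiplicative log-uniform factor in [1/2, 2], reflected into [0.01, 8];
the transport direction flips).  Independently of reproduction, every
living cell can each step acquire a gene from a random occupied Moore
neighbour (HGT, 5·10⁻⁴) or discover a uniformly random reaction with
random parameters (10⁻⁴).

The environment adds resource influx (0.002 per site-step for R only),
first-order degradation, and 4-neighbour discrete-Laplacian diffusion
with toroidal wrap; a well-mixed mode replaces diffusion by setting every
site to the global mean.  Lineages are tracked with renewing neutral
markers (all cells get fresh unique markers whenever one marker fixes),
and metabolic genotypes — the 59-bit presence/absence vector of reactions,
ignoring copy number and parameters — are organised into a clade phylogeny
for Muller-style visualisation.

## Step ordering

The order of operations inside one time step is: (1) ODE update of all
cells coupled to their local pools; (2) environmental influx, degradation
and diffusion (or mixing); (3) toxicity accumulation, stochastic death and
lysis; (4) reproduction lotteries over shuffled empty sites; (5) HGT and
gene discovery; (6) marker renewal; (7) recording.  The exact sub-step
order within a time step is a modelling choice; results at the population
level are not expected to be sensitive to it, but it is fixed and
documented here for reproducibility.

## Numerical integration

Within the cell-update phase, cells interact only with their own site's
pools, so the population decomposes into independent small ODE systems
(one per occupied site; dimension 2 + 9 + n_genes + 9).  These systems are
stiff — an evolved gene with v_max near 8, protein level of order 10 and a
Michaelis constant near 0.01 yields linearised rates of order 10³–10⁴ per
step — so explicit solvers are impractical.

Two integration paths exist:

* `cell.integrate_cell` advances a single cell with scipy's LSODA at
  rtol 10⁻⁶ / atol 10⁻⁹.  This is the reference path used by the
  closed-form physiology tests.
* The population stepper uses a compiled (numba) per-cell implicit solver:
  adaptive backward Euler with a modified-Newton iteration, a
  finite-difference Jacobian reused across substeps, a factored iteration
  matrix that is only rebuilt when the step size drifts more than 30%, and
  a free local-error estimate (h/2)·(f₁−f₀) controlled by a weighted-RMS
  test at rtol 3·10⁻⁴ / atol 10⁻⁶ by default (absolute errors of 10⁻⁶ concentration units sit three orders of magnitude below the smallest dynamically relevant scale, the ~2·10⁻³ per-site resource pool).  Each cell remembers its
  accepted step size across scheduler steps.  Agreement with the LSODA
  path is checked in the test suite (relative differences ≲10⁻³ per step
  at these tolerances, which is far below the stochastic variability of
  the population process).

Concentrations are clamped at zero inside every rate law, so small
negative excursions decay instead of amplifying; state is clamped at zero
after each step.  Non-finite states abort the run with a cell diagnostic.

## Parameters without printed values

The physiology requires several constants beyond the published chemistry
and mutation tables.  They default to: growth rate g = 1.0, shrink rate
s_shrink = 0.01, Vol_max = 1.0, division volume 0.5, starvation volume
0.05, toxicity scaling s_tox = 1.0 (a distinct parameter from the shrink
rate — two distinct parameters that share the symbol *s* in the
standard notation), budget
degradation 0.01, protein degradation 0.1, B_pop averaging horizon 100
steps.  All are exposed in `DynamicsParams`.  The defaults were chosen
once so that a founder cell divides within a few steps and founder
communities persist indefinitely; with them the model's per-step division
probability and ~0.03 death rate give population turnover broadly
consistent with the published ratio of about 2.5 steps per generation.

Founder cells start with volume 0.3, budget 0.01, a small bootstrap stock
of internal metabolites (E = 0.05, B1 = B2 = 0.02 — deliberately below
every toxicity threshold, which sit at concentrations of 0.05–0.16), and
external resource pools at 0.1 per site.  Passive membrane diffusion
reuses the per-metabolite environmental diffusion rates (the table gives
one diffusion constant per metabolite; the model applies it both between
grid sites and across the membrane), scalable via
`membrane_diffusion_scale`.

## What the synthetic communities emulate

The package ships two engineered communities used to validate the
dependency assay, built from hand-parameterised genomes rather than
evolution:

* **crossfeeders** — strain A imports R, converts it to B1 (+E), exports
  B1 and imports B2; strain B is the mirror image.  By construction each
  strain lacks the partner's building-block synthesis, so the pair is
  obligately co-dependent: removing either lineage drives the other
  extinct within the 2000-step assay window.
* **major_minor** — the major lineage synthesises both blocks (B2 only
  weakly) and imports B2; the minor lineage specialises in B2, exports it
  and scavenges B1 from major-lineage lysis.  This reproduces the evolved
  phenomenology: the minor lineage is obligate, while the major survives
  alone but at visibly lower community production than it achieved in the
  partnership.

These fixtures capture the *interaction structure* of evolved
cross-feeders, not their genetic diversity: real evolved communities carry
standing variation, multiple genotypes per lineage and rare autonomous
mutants, which the fixtures only acquire when briefly evolved with
mutation switched on.  Tests passing on them demonstrate that the assay
machinery and the ecological feedbacks behave as designed, not that
evolution at full scale must produce identical numbers.

## Dependency assays

A dependency test removes every cell of one renewing-marker lineage
(without lysis — their internal metabolites leave the system), zeroes all
mutation, HGT and discovery rates, and continues the simulation for at
most 2000 steps or to extinction.  Community production (the summed biomass
production rate over living cells) is recorded immediately before removal —
both in total and restricted to the remaining lineage — and again 1500
steps after removal.  The published description uses a 2000-step cap while
the corresponding figure measures production 1500 steps after removal;
both values are kept, as the cap and the measurement point respectively,
and both are arguments of `dependency_test`.

"Lineage" here always means a renewing-marker lineage, not a
metabolic-genotype clade.

## Problem sizes

The full published campaign (60 replicates × 10⁶ steps on a 45×45 grid)
is cluster-scale.  The test suite instead runs the complete model at
reduced sizes chosen to exercise every mechanism: a 15×15 grid for
2×10⁴ steps for the evolution smoke test (population persistence, rising
production, fixation of a dedicated energy reaction, classifiable network
topology), and 10×10–12×12 grids for the dependency-assay campaigns
(≥20 assays across briefly evolved replicates of the engineered
cross-feeding community).  Stochastic rate recoveries (death rate 0.03,
point-mutation rate 0.02, HGT rate 5·10⁻⁴, stretch-length parameter 0.3)
use ≥10⁵ trials each.

## Known limitations

* Transcription-factor regulation is omitted entirely.
* The artificial chemistry is not mass-balanced (by design, following the
  published reaction table), so "conservation" checks apply to transport,
  diffusion and degradation, not to catalysis.
* The Muller-table cutoff folds rare clades into their nearest surviving
  ancestor; pruned root lines fall back to the earliest surviving clade,
  which slightly overstates that clade's abundance in pathological
  phylogenies.
* The operator-split step (cells first, then environment) introduces an
  O(dt) splitting error at dt = 1; this is part of the model definition
  here, not a numerical tolerance.
* At desk scale the evolved communities are small (~10² cells), so
  production comparisons in dependency assays carry substantial sampling
  noise compared to the published 45×45 populations.
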