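# Methods

`ecoconnect` models how water currents shape population genetic structure in
a closed aquatic basin.  It chains four stages: a parametric circulation over
a stylized lake, Lagrangian particle tracking that turns circulation into
larval dispersal probabilities, a forward-time eco-genetic agent-based model
(ABM) that turns dispersal into multilocus genotypes, and a fit-evaluation
layer that asks which dispersal regime best explains an observed pattern of
genetic differentiation.

## The stylized domain

The domain is a closed rectangular basin, 150 km x 500 km, with bathymetric
depth increasing linearly from the shoreline to 100 m along the centerline.
The long axis mimics the ~500 km latitudinal extent of a large temperate
lake; no coastline data are used.  The shoreline is divided into `n_regions`
(default 40) equal arcs, and every interior point belongs to the region
owning its nearest shoreline point, yielding roughly equal-area,
shoreline-anchored polygons analogous to a sampling-grid partition.

Circulation superposes three motifs of large stratified lakes:

* an **alongshore jet** — peak speed `alongshore_speed`, flowing
  counterclockwise, decaying offshore with a 20 km e-folding width;
* **two stationary gyres** (cyclonic south, anticyclonic north) derived from
  a Gaussian stream function, hence exactly divergence-free, with peak speed
  `gyre_strength`;
* **temporally correlated noise** — a spatially uniform Ornstein-Uhlenbeck
  velocity with stationary SD `noise_amplitude` and a 2-day decorrelation
  time, precomputed hourly from the scenario seed so that velocity sampling
  is bitwise reproducible.

Vertical mixing uses a two-layer diffusivity profile: 10^-3 m^2/s in the
epilimnion (upper 10 m), 10^-5 m^2/s below, blended by a tanh transition of
3 m width.  These magnitudes are standard for a stratified temperate lake in
summer; they are declared defaults, not fitted values.  Horizontal
velocities attenuate smoothly with depth and vanish outside the basin.

"Dispersive" scenarios (fast jet) and "retentive" scenarios (still water,
local diffusion only) are both reachable by varying `alongshore_speed`
alone, which is how the candidate-scenario grids are built.

## Particle tracking

Larvae are released at shoreline nodes where depth < 10 m (100 particles per
node by default), uniformly distributed through the local water column, and
tracked for the pelagic larval duration (PLD; 30/40/50 days at full scale).
The horizontal step is Euler-Maruyama: advection plus `sqrt(2 K_h dt)`
Gaussian noise per axis, with `K_h = 5.6 m^2/s` and `dt = 360 s` by default.
The vertical step is the Visser diffusivity-gradient-corrected random walk
(drift `K_v'(z) dt`, diffusion evaluated at `z + K_v'(z) dt / 2`), which is
unbiased under vertically varying `K_v`; a configuration whose `dt` exceeds
half the curvature timescale `1/max|K_v''|` is rejected with a diagnostic.
An optional deterministic upward swimming velocity (`w_swim = 0.0003 m/s`)
is added to the vertical step; it is sufficient to hold released particles
in the epilimnion, which the test suite checks directly (>= 90% of particles
released through a 50 m column end above 10 m after two days).

All boundaries are reflective: the basin is closed, so connectivity rows sum
to exactly 1 and particle counts are conserved.  End positions are binned by
region: `P[i, f] = N_if / N_i`.  Rows of regions that released no particles
are flagged invalid rather than zero-filled so that downstream column
normalization can detect them.  Region assignment of end positions uses the
same nearest-shoreline rule as the partition; ties break toward the
lower-index region.

Summary metrics per matrix: **mean connectivity** (mean over origins of the
count of destination regions reached), **mean retention** (mean diagonal)
and, when the driving flow is available, **mean current strength**, defined
here as the domain- and time-averaged horizontal speed at mid-epilimnion
depth (no standard formula exists for this quantity; the definition is the
package's own and is labeled as such).

## The eco-genetic agent-based model

Each of 40 local populations (default) holds diploid, aged, sexed
individuals with 100 unlinked biallelic loci initialized in Hardy-Weinberg
proportions (per-locus initial frequencies drawn Uniform(0.1, 0.9) unless
supplied) and ages drawn from the stationary geometric age distribution.
Each model year applies, in order: **mortality** (independent 20%/year;
survivors age), **reproduction**, **larval dispersal** and **recruitment**.

Reproduction pairs males and females within each population at random
without replacement.  Each pair draws a gamma(shape 0.5, rate 0.1) fecundity
weight, and the offspring its population must supply are allocated to pairs
multinomially in proportion to the weights.  Using the gamma draws as
allocation weights — rather than rounding them to counts — simultaneously
realizes the intended high variance in reproductive success (most pairs
produce nothing; the test suite verifies among-pair overdispersion well
above Poisson) and meets the recruitment demand exactly.  Inheritance is
strictly Mendelian; offspring sex is uniform.

Dispersal is destination-driven: each population's demand (deaths to replace,
plus a Normal(0, 105) deviate truncated at zero and capped at 1.5x local
carrying capacity) is drawn from origin populations by a multinomial over
the destination's connectivity-matrix *column*, normalized over origins.
The demand deviate's SD of 105 is an absolute count, so its relative effect
shrinks with population size; size-regulation checks are therefore stated at
the full 40,000-capacity scale, where the long-run mean stays within 5% of
capacity.  The multinomial is resolved before reproduction (so each origin
knows exactly how many offspring to create), but larvae move only after
reproduction; only new recruits disperse — adults never move.  An all-zero
column is logged and receives no recruits, surfacing local-extinction risk
instead of hiding it.  When a *set* of matrices is configured, one matrix is
redrawn uniformly with replacement each model year.

There is no mutation, selection, adult movement or site-specific demography.
Differentiation therefore emerges purely from the drift/gene-flow balance,
and several emergent properties calibrate the demography:

* mean generation time (mean parental age at the birth of recruited
  offspring, after a 50-year burn-in) settles near 5 years under 20%
  mortality with all age >= 1 individuals eligible to mate — consistent with
  geometric survivorship, whose mean adult age is 1/0.2 = 5;
* allele frequencies are a martingale (no systematic drift bias across
  replicates);
* expected heterozygosity under a fully retentive matrix decays like
  `(1 - 1/(2 N_e))` per generation with `N_e` proportional to census size
  but well below it, as expected under sweepstakes-like gamma(0.5)
  reproductive skew.

A single root seed drives every draw via one generator, so identical
(parameters, seed) reproduce results exactly.

## F_ST and fit evaluation

Differentiation is the Weir & Cockerham (1984) theta, computed per pair of
sites from the per-locus a/b/c variance components and combined across loci
as a ratio of sums (never a mean of per-locus ratios).  A locus enters a
pair only if both sites have >= 2 genotyped individuals there; loci
monomorphic across the pair contribute nothing; negative estimates are
retained.  The implementation is validated against an exact-fraction hand
computation of the two-population formulas on a toy genotype table.

Predictive (model) and empirical F_ST matrices are compared by OLS of
empirical on predictive over all site pairs (the regression direction
matches plotting predictive on the x-axis).  Reported per cell: slope,
adjusted R^2, Spearman rho, and the composite

    gof = 1 - sqrt(((slope - 1)^2 + (adj_R2 - 1)^2) / 2),

the rescaled Euclidean distance from the perfect point (1, 1).  This
scalarization is the package's own declared formula; all grid-level
conclusions use ranks (top-fraction shares, eta-squared), which are robust
to any monotone redefinition.  Parameter attribution uses (a) the share of
each tested value among the top 20% of cells by gof and (b) a one-way
eta-squared decomposition of gof by parameter level, in percent.

## Pseudo-empirical panels

Field genotype panels are emulated by running the ABM to quasi-equilibrium
under a designated "truth" connectivity matrix and sampling `n_per_site`
individuals per site into a GT-only VCF (site labels encoded in sample IDs
as `SITE_<region>_<nnn>`, since VCF has no population field).  A dispersive
truth matrix yields weak differentiation (mean pairwise F_ST near 0.003 or
below, like a well-mixed main basin); a near-closed truth matrix yields
strong differentiation (> 0.05, like a semi-isolated embayment).  What
passing tests show is that the *pipeline logic* recovers a known dispersal
regime from genotypes it generated itself; they cannot show that the
stylized circulation matches any real lake, that RAD-Seq genotyping error is
handled (the panels are error-free), or that 100 loci behave like a
genome-wide panel.

## Desk-scale experiment and problem sizes

The full factorial (216 tracking runs; 4536 ABM cells x 100 replicates)
is enumerated exactly but not executed by default.  The shipped experiment
runs a reduced, desk-scale analogue chosen once: 20 regions / 20 local
populations of 250 individuals, 100 loci, 60 model years, a 10-day PLD with
50 particles per release node, and six candidate circulation scenarios with
alongshore speeds {0, 0.03, 0.06, 0.10, 0.15, 0.22} m/s (retentive ->
dispersive), 20 replicates per candidate for headline checks.  Child seeds
are SHA-256-derived from the root seed and each cell's coordinates (63-bit,
verified collision-free across the full-scale grid), and completed cells are
persisted and skipped on rerun.

Generation-time acceptance uses the full demographic configuration (40
populations, local N = 900 — the mean of the tested sizes — 200 model
years, 50-year burn-in, 10 replicate seeds).

## Known limitations

* The circulation is parametric and spatially smooth; there is no wind
  forcing, no inter-basin exchange, no unstructured mesh, and the noise is
  spatially uniform.
* The partition is shoreline-anchored by construction; offshore "interior"
  regions do not exist, unlike a general polygon grid.
* Reflective boundaries preclude loss from the domain, so connectivity rows
  always sum to 1; open boundaries would need an explicit outflow rule.
* The ABM omits mutation, selection, linkage, adult movement and
  site-specific demography by design.
* The composite gof is one of many reasonable scalarizations; conclusions
  that depend on its cardinal values (rather than ranks) should not be drawn.
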