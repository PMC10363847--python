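# ecoconnect

**Biophysical larval dispersal + eco-genetic agent-based modeling of
population connectivity in closed aquatic basins.**

Many lake and coastal fishes disperse almost exclusively as drifting larvae,
so the currents in the weeks after spawning — not adult movement — set the
balance of gene flow and genetic drift among local populations.  Direct
observation of larval transport is rarely possible.  `ecoconnect` implements
the indirect route: simulate transport, convert it into dispersal
probabilities, push those probabilities through an explicit eco-genetic
model, and ask which simulated circulation regime best reproduces an
observed pattern of genetic differentiation.

The package is aimed at population geneticists and larval ecologists who
want a desk-scale, fully reproducible version of that pipeline:

1. **`synthetic_domain`** — a stylized closed basin (150 km x 500 km,
   depth-ramped bathymetry), a shoreline-anchored partition into `n`
   regions, parametric 3-D circulation (alongshore jet + divergence-free
   gyres + Ornstein-Uhlenbeck noise over a two-layer vertical diffusivity),
   nearshore release sites, and pseudo-empirical genotype panels of known
   dispersal provenance;
2. **`particle_tracking`** — Euler-Maruyama advection-diffusion with a
   Visser vertical random walk and optional upward larval swimming;
   end positions become the connectivity matrix `P[i, f] = N_if / N_i`;
3. **`eco_genetic`** — a forward-time agent-based model: overlapping
   generations, 20%/yr mortality, gamma-overdispersed reproductive success,
   Mendelian inheritance at 100 unlinked SNPs, and multinomial
   larval dispersal over the connectivity matrix (annual order: mortality ->
   reproduction -> dispersal -> recruitment);
4. **`popgen`** — Weir & Cockerham (1984) pairwise F_ST (ratio-of-sums
   across loci, negative estimates retained), heterozygosity, VCF I/O;
5. **`fit_evaluation`** — OLS of empirical on predictive F_ST over all site
   pairs; slope, adjusted R², Spearman ρ, and the composite
   `gof = 1 − sqrt(((slope−1)² + (R²−1)²)/2)`; top-fraction parameter shares
   and eta-squared variance attribution over factorial grids;
6. **`experiment` / `ecoconnect` CLI** — factorial grid enumeration
   (216 tracking configurations; 4536 eco-genetic combinations, 453,600 runs
   at 100 replicates), SHA-256 seed derivation, and a resumable desk-scale
   end-to-end experiment.

See `docs/methods.md` for the model descriptions, defaults and limitations.

## Worked example

Track larvae under a strongly dispersive circulation (0.22 m/s alongshore
jet), then drive the eco-genetic model with the resulting matrix:

```bash
$ ecoconnect track --n-regions 20 --particles-per-site 50 --pld-days 10 \
    --alongshore-speed 0.22 --gyre-strength 0.03 --noise-amplitude 0.03 \
    --seed 11 --out disp.csv
wrote 20x20 matrix to disp.csv (mean connectivity 2.30, mean retention 0.000,
mean current 0.0522 m/s)

$ ecoconnect simulate --matrix disp.csv --model-years 100 --local-n 900 --seed 11
ran 100 years; final size 18374; mean generation time 5.05 y; mean pairwise F_ST 0.0008
```

Reading the numbers: after a 10-day drift each origin region seeds on
average 2.3 regions and retains essentially none of its own larvae
(retention 0.000) — transport is dominated by the jet.  A century of that
dispersal regime leaves the 20 populations nearly panmictic: mean pairwise
F_ST ≈ 0.0008, the weak differentiation characteristic of well-connected
main-basin populations.  The emergent mean generation time of ≈ 5 years
follows from 20%/yr mortality with all adults eligible to mate.  Re-running
either command with the same seed reproduces these numbers exactly.

The full desk-scale experiment — six candidate circulation scenarios from
retentive to dispersive, a pseudo-empirical panel generated under the most
dispersive one, and replicate eco-genetic runs scored against it — runs as

```bash
ecoconnect grid --seed 1 --out-dir results_grid
```

and prints the candidate ranking by mean goodness of fit together with the
Spearman correlation between fit and mean connectivity.  The designated
truth scenario ranks first and the correlation is positive: dispersal
regimes are identifiable from the genetic pattern they generate.

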