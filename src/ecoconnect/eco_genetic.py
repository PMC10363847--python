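"""Forward-time, spatially explicit eco-genetic agent-based model.

The model tracks diploid, aged, sexed individuals carrying unlinked biallelic
loci across a set of local populations connected by larval dispersal.  Each
model year applies, in order:

1. **mortality** — every individual dies independently with probability
   ``mortality_rate`` (default 20%/year); survivors age by one year;
2. **reproduction** — within each local population, males and females are
   paired at random without replacement; each pair receives a gamma(shape
   0.5, rate 0.1) fecundity weight, and the offspring a population must
   supply are allocated to its pairs multinomially in proportion to those
   weights (most pairs contribute nothing — high variance in reproductive
   success); inheritance is strictly Mendelian;
3. **larval dispersal** — each destination's recruitment demand (deaths, plus
   a Normal(0, ``recruit_sd``) deviate that makes local sizes fluctuate) is
   drawn from the origin populations by a multinomial over the destination's
   connectivity-matrix column;
4. **recruitment** — the newly created age-0 offspring join their destination
   populations.

Only recruits disperse; adults never move.  There is no mutation or
selection, so among-population differentiation (pairwise Weir-Cockerham
F_ST of the final-year genotypes) emerges purely from the drift/gene-flow
balance imposed by the connectivity matrix.  With 20% annual mortality and
all age >= 1 individuals reproductively eligible, the emergent mean
generation time — the mean parental age at the birth of recruited
offspring — is about 5 years.

For efficiency, each local population is stored as a struct of numpy arrays
and every stochastic step is vectorized; a single root seed drives all draws,
so identical (parameters, seed) reproduce identical results bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from ecoconnect.particle_tracking import ConnectivityMatrix

logger = logging.getLogger(__name__)

FEMALE, MALE = 0, 1

#: local sizes may transiently exceed carrying capacity by at most this factor
HABITAT_CAP_FACTOR = 1.5


@dataclass(frozen=True)
class DemographyConfig:
    """Demographic and genetic parameters of one simulation.

    ``recruit_sd`` is the standard deviation of the annual normal deviate on
    each population's recruitment demand (mean = deaths to replace); it
    drives realistic year-class fluctuations in local abundance.
    ``init_allele_freq`` optionally fixes the per-locus initial alternate
    allele frequencies; by default each locus draws p ~ Uniform(0.1, 0.9)
    from the simulation seed.
    """

    mortality_rate: float = 0.2  # per year
    recruit_sd: float = 105.0
    gamma_shape: float = 0.5
    gamma_rate: float = 0.1
    n_loci: int = 100
    init_allele_freq: Optional[Sequence[float]] = None
    model_years: int = 100
    burn_in_years: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mortality_rate < 1.0:
            raise ValueError("mortality_rate must lie in [0, 1)")
        if self.gamma_shape <= 0 or self.gamma_rate <= 0:
            raise ValueError("gamma shape and rate must be positive")
        if self.recruit_sd < 0:
            raise ValueError("recruit_sd must be non-negative")
        if self.init_allele_freq is not None:
            p = np.asarray(self.init_allele_freq, dtype=float)
            if len(p) != self.n_loci:
                raise ValueError("init_allele_freq must have one entry per locus")
            if ((p <= 0) | (p >= 1)).any():
                raise ValueError("initial allele frequencies must lie in (0, 1)")


@dataclass
class LocalPopulation:
    """One local population as parallel per-individual arrays."""

    index: int  # 1-based, matches connectivity-matrix regions
    carrying_capacity: int
    age: np.ndarray  # int32, years
    sex: np.ndarray  # uint8, FEMALE/MALE
    genotypes: np.ndarray  # uint8 (n, n_loci, 2), alleles in {0, 1}
    natal: np.ndarray  # int32, natal population index

    @property
    def size(self) -> int:
        return len(self.age)

    def keep(self, mask: np.ndarray) -> None:
        self.age = self.age[mask]
        self.sex = self.sex[mask]
        self.genotypes = self.genotypes[mask]
        self.natal = self.natal[mask]

    def add(self, age, sex, genotypes, natal) -> None:
        self.age = np.concatenate([self.age, age])
        self.sex = np.concatenate([self.sex, sex])
        self.genotypes = np.concatenate([self.genotypes, genotypes])
        self.natal = np.concatenate([self.natal, natal])


@dataclass
class Metapopulation:
    """All local populations plus the shared locus panel."""

    populations: list[LocalPopulation]
    n_loci: int

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    @property
    def total_size(self) -> int:
        return sum(p.size for p in self.populations)

    def sizes(self) -> np.ndarray:
        return np.array([p.size for p in self.populations])

    def to_genotype_table(self):
        """All individuals as a dosage table, site label = SITE_<index>."""
        from ecoconnect.popgen import GenotypeTable

        dosage = np.concatenate(
            [p.genotypes.sum(axis=2) for p in self.populations]
        ).astype(np.int8)
        sites = np.concatenate(
            [np.full(p.size, f"SITE_{p.index}", dtype=object) for p in self.populations]
        )
        loci = [f"L{j + 1:04d}" for j in range(self.n_loci)]
        return GenotypeTable(dosage, sites, loci)

    def allele_frequencies(self) -> np.ndarray:
        """Metapopulation-wide alternate-allele frequency per locus."""
        total = sum(p.genotypes.sum(axis=(0, 2), dtype=np.int64) for p in self.populations)
        return total / (2.0 * self.total_size)


def _stationary_ages(n: int, mortality: float, rng: np.random.Generator) -> np.ndarray:
    """Ages drawn from the geometric age distribution implied by survival."""
    if mortality == 0.0:
        return np.ones(n, dtype=np.int32)
    return rng.geometric(mortality, size=n).astype(np.int32)


def init_metapopulation(
    cfg: DemographyConfig,
    pop_sizes: Union[int, Sequence[int]],
    n_pops: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Metapopulation:
    """Create a metapopulation in Hardy-Weinberg and age-structure equilibrium.

    Each individual's genotype is drawn locus-wise as two independent
    Bernoulli(p_l) alleles; sexes are i.i.d. uniform; ages follow the
    stationary (geometric) age distribution implied by the mortality rate.
    """
    if isinstance(pop_sizes, (int, np.integer)):
        if n_pops is None:
            raise ValueError("n_pops is required when pop_sizes is a scalar")
        pop_sizes = [int(pop_sizes)] * n_pops
    pop_sizes = [int(s) for s in pop_sizes]
    if any(s <= 0 for s in pop_sizes):
        raise ValueError("all population sizes must be positive")
    rng = rng or np.random.default_rng(cfg.seed)
    if cfg.init_allele_freq is not None:
        p = np.asarray(cfg.init_allele_freq, dtype=float)
    else:
        p = rng.uniform(0.1, 0.9, size=cfg.n_loci)
    pops = []
    for k, size in enumerate(pop_sizes):
        geno = (
            rng.random((size, cfg.n_loci, 2)) < p[None, :, None]
        ).astype(np.uint8)
        pops.append(
            LocalPopulation(
                index=k + 1,
                carrying_capacity=size,
                age=_stationary_ages(size, cfg.mortality_rate, rng),
                sex=rng.integers(0, 2, size=size, dtype=np.uint8),
                genotypes=geno,
                natal=np.full(size, k + 1, dtype=np.int32),
            )
        )
    return Metapopulation(pops, cfg.n_loci)


def apply_mortality(
    metapop: Metapopulation,
    cfg: DemographyConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Kill each individual independently with ``mortality_rate``; age survivors.

    Returns the per-population death counts, which define each population's
    replacement recruitment demand for the year.
    """
    deaths = np.zeros(metapop.n_pops, dtype=int)
    for k, pop in enumerate(metapop.populations):
        survive = rng.random(pop.size) >= cfg.mortality_rate
        deaths[k] = pop.size - survive.sum()
        pop.keep(survive)
        pop.age += 1
    return deaths


def reproduce(
    pop: LocalPopulation,
    n_offspring: int,
    cfg: DemographyConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Produce ``n_offspring`` genotypes by gamma-weighted multinomial mating.

    Mature (age >= 1) males and females are paired monogamously at random
    without replacement; each pair's share of the brood is multinomial with
    probability proportional to its gamma(shape, rate) fecundity weight.
    Offspring inherit one allele per locus from each parent uniformly at
    random (strict Mendelian inheritance) and are assigned uniform random sex.

    Returns ``(genotypes, sexes, parental_ages)`` where ``parental_ages``
    stacks the mother's and father's age at birth for every offspring (so it
    has ``2 * n_offspring`` entries).  A population lacking either sex
    produces no offspring (logged).
    """
    if n_offspring <= 0:
        empty_g = np.empty((0, cfg.n_loci, 2), dtype=np.uint8)
        return empty_g, np.empty(0, dtype=np.uint8), np.empty(0, dtype=np.int32)
    mature = pop.age >= 1
    males = np.flatnonzero(mature & (pop.sex == MALE))
    females = np.flatnonzero(mature & (pop.sex == FEMALE))
    n_pairs = min(len(males), len(females))
    if n_pairs == 0:
        logger.warning(
            "population %d has no mating pairs (males=%d, females=%d); "
            "produced 0 of %d requested offspring",
            pop.index, len(males), len(females), n_offspring,
        )
        empty_g = np.empty((0, cfg.n_loci, 2), dtype=np.uint8)
        return empty_g, np.empty(0, dtype=np.uint8), np.empty(0, dtype=np.int32)
    fathers = rng.permutation(males)[:n_pairs]
    mothers = rng.permutation(females)[:n_pairs]
    weights = rng.gamma(cfg.gamma_shape, 1.0 / cfg.gamma_rate, size=n_pairs)
    total = weights.sum()
    if total <= 0.0:  # numerically degenerate gamma draws
        weights = np.ones(n_pairs)
        total = float(n_pairs)
    brood = rng.multinomial(n_offspring, weights / total)
    pair_of = np.repeat(np.arange(n_pairs), brood)

    mo = mothers[pair_of]
    fa = fathers[pair_of]
    k = n_offspring
    geno = np.empty((k, cfg.n_loci, 2), dtype=np.uint8)
    pick_m = rng.integers(0, 2, size=(k, cfg.n_loci, 1), dtype=np.int8)
    pick_f = rng.integers(0, 2, size=(k, cfg.n_loci, 1), dtype=np.int8)
    geno[:, :, 0:1] = np.take_along_axis(pop.genotypes[mo], pick_m, axis=2)
    geno[:, :, 1:2] = np.take_along_axis(pop.genotypes[fa], pick_f, axis=2)
    sexes = rng.integers(0, 2, size=k, dtype=np.uint8)
    parental_ages = np.concatenate([pop.age[mo], pop.age[fa]]).astype(np.int32)
    return geno, sexes, parental_ages


def disperse_recruits(
    demand: np.ndarray,
    matrix: ConnectivityMatrix,
    rng: np.random.Generator,
    recruit_sd: float = 0.0,
) -> np.ndarray:
    """Draw origin counts for each destination's recruitment demand.

    For destination ``f``, the number of recruits is
    ``demand[f] + round(Normal(0, recruit_sd))`` truncated at zero, and their
    origins are multinomial over column ``f`` of the connectivity matrix
    (normalized over origins).  An all-zero column means no population can
    supply that destination: it receives zero recruits that year (logged), so
    local extinction risk surfaces rather than being hidden.

    Returns an (n_pops, n_pops) integer array ``counts[i, f]``.
    """
    P = matrix.P
    n = P.shape[0]
    demand = np.asarray(demand)
    if demand.shape != (n,):
        raise ValueError("demand must have one entry per population")
    if (demand < 0).any():
        raise ValueError("recruitment demand must be non-negative")
    counts = np.zeros((n, n), dtype=np.int64)
    for f in range(n):
        want = int(demand[f])
        if recruit_sd > 0:
            want += int(round(rng.normal(0.0, recruit_sd)))
        want = max(want, 0)
        if want == 0:
            continue
        col = P[:, f]
        mass = col.sum()
        if mass <= 0.0:
            logger.warning(
                "destination %d has zero connectivity column mass; "
                "no recruits this year", f + 1,
            )
            continue
        counts[:, f] = rng.multinomial(want, col / mass)
    return counts


MatrixSet = Sequence[ConnectivityMatrix]


@dataclass
class SimulationResult:
    """Final state and per-year records of one simulation run."""

    metapopulation: Metapopulation
    pop_sizes_by_year: np.ndarray  # (years, n_pops)
    parental_age_sum: np.ndarray  # (years,)
    parental_age_count: np.ndarray  # (years,)
    fst: "object"  # FstMatrix of the final-year genotypes (all individuals)
    config: DemographyConfig
    seed: int
    years_run: int
    extinct: bool = False


def run_simulation(
    matrices: Union[ConnectivityMatrix, MatrixSet],
    cfg: DemographyConfig,
    local_n: Union[int, Sequence[int]] = 900,
    compute_fst: bool = True,
    year_hook: Optional[Callable[[str, int, Metapopulation], None]] = None,
) -> SimulationResult:
    """Run the annual mortality -> reproduction -> dispersal -> recruitment loop.

    ``matrices`` is a single connectivity matrix, applied every year, or a
    sequence (matrix set) from which one matrix is drawn uniformly with
    replacement each model year before the reproduction step.  ``local_n``
    sets each population's carrying capacity.  ``year_hook``, when given, is
    called as ``hook(stage, year, metapop)`` after every stage (for
    step-order instrumentation).

    The returned result carries per-year population sizes, per-year parental
    age records (for generation-time estimation) and, unless disabled, the
    pairwise Weir-Cockerham F_ST of all final-year individuals — the model's
    "predictive" differentiation.
    """
    if isinstance(matrices, ConnectivityMatrix):
        matrix_set: list[ConnectivityMatrix] = [matrices]
    else:
        matrix_set = list(matrices)
        if not matrix_set:
            raise ValueError("matrix set must contain at least one matrix")
    n_pops = matrix_set[0].P.shape[0]
    if any(m.P.shape[0] != n_pops for m in matrix_set):
        raise ValueError("all matrices in a set must share dimensions")

    rng = np.random.default_rng(cfg.seed)
    metapop = init_metapopulation(cfg, local_n, n_pops=n_pops, rng=rng)
    capacities = np.array([p.carrying_capacity for p in metapop.populations])

    years = cfg.model_years
    sizes = np.zeros((years, n_pops), dtype=int)
    age_sum = np.zeros(years)
    age_count = np.zeros(years)
    extinct = False
    year = 0
    for year in range(years):
        deaths = apply_mortality(metapop, cfg, rng)
        if year_hook:
            year_hook("mortality", year, metapop)
        if metapop.total_size == 0:
            logger.error("metapopulation extinct at year %d; stopping early", year)
            extinct = True
            break

        if len(matrix_set) > 1:
            matrix = matrix_set[rng.integers(len(matrix_set))]
        else:
            matrix = matrix_set[0]

        # the dispersal multinomial is resolved before offspring are created
        # so each origin knows exactly how many offspring to produce; the
        # actual movement of larvae still happens after reproduction
        current = metapop.sizes()
        demand = np.maximum(capacities - current, 0)
        counts = disperse_recruits(demand, matrix, rng, cfg.recruit_sd)
        # cap recruitment at available habitat
        room = np.maximum(
            (HABITAT_CAP_FACTOR * capacities).astype(int) - current, 0
        )
        for f in range(n_pops):
            total_f = counts[:, f].sum()
            if total_f > room[f] and total_f > 0:
                scaled = np.floor(counts[:, f] * (room[f] / total_f)).astype(np.int64)
                counts[:, f] = scaled

        # reproduction in each origin population
        recruits_by_dest: dict[int, list] = {f: [] for f in range(n_pops)}
        for i, pop in enumerate(metapop.populations):
            k_i = int(counts[i].sum())
            if k_i == 0:
                continue
            geno, sexes, par_ages = reproduce(pop, k_i, cfg, rng)
            produced = len(sexes)
            if produced == 0:
                continue
            age_sum[year] += par_ages.sum()
            age_count[year] += len(par_ages)
            dests = np.repeat(np.arange(n_pops), counts[i])
            dests = rng.permutation(dests)[:produced]
            for f in np.unique(dests):
                rows = dests == f
                recruits_by_dest[int(f)].append(
                    (geno[rows], sexes[rows], rows.sum(), i + 1)
                )
        if year_hook:
            year_hook("reproduction", year, metapop)
            year_hook("dispersal", year, metapop)

        # recruitment: age-0 offspring join their destination populations
        for f, chunks in recruits_by_dest.items():
            if not chunks:
                continue
            pop = metapop.populations[f]
            geno = np.concatenate([c[0] for c in chunks])
            sexes = np.concatenate([c[1] for c in chunks])
            natal = np.concatenate(
                [np.full(c[2], c[3], dtype=np.int32) for c in chunks]
            )
            pop.add(np.zeros(len(sexes), dtype=np.int32), sexes, geno, natal)
        if year_hook:
            year_hook("recruitment", year, metapop)

        sizes[year] = metapop.sizes()

    fst = None
    if compute_fst and not extinct:
        from ecoconnect.popgen import pairwise_fst

        fst = pairwise_fst(metapop.to_genotype_table())

    return SimulationResult(
        metapopulation=metapop,
        pop_sizes_by_year=sizes[: year + 1],
        parental_age_sum=age_sum[: year + 1],
        parental_age_count=age_count[: year + 1],
        fst=fst,
        config=cfg,
        seed=cfg.seed,
        years_run=year + 1,
        extinct=extinct,
    )


def mean_generation_time(
    result: SimulationResult, burn_in: Optional[int] = None
) -> float:
    """Mean parental age at the birth of recruited offspring, after burn-in.

    Averages over every parental-age record (mothers and fathers of every
    recruited offspring) in the years following ``burn_in`` (default: the
    configuration's ``burn_in_years``).
    """
    burn = result.config.burn_in_years if burn_in is None else burn_in
    s = result.parental_age_sum[burn:]
    c = result.parental_age_count[burn:]
    if c.sum() == 0:
        raise ValueError("no parental-age records after burn-in")
    return float(s.sum() / c.sum())
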