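"""Demography, inheritance, dispersal and emergent genetics of the ABM."""

import numpy as np
import pytest
from scipy import stats

from ecoconnect import eco_genetic as eg
from ecoconnect import particle_tracking as pt
from ecoconnect import popgen


def make_pop(genotypes, sexes, ages=None, index=1):
    n = len(sexes)
    return eg.LocalPopulation(
        index=index,
        carrying_capacity=n,
        age=np.asarray(ages if ages is not None else np.ones(n), dtype=np.int32),
        sex=np.asarray(sexes, dtype=np.uint8),
        genotypes=np.asarray(genotypes, dtype=np.uint8),
        natal=np.full(n, index, dtype=np.int32),
    )


class TestInit:
    def test_hwe_heterozygosity_at_half(self):
        cfg = eg.DemographyConfig(n_loci=1, init_allele_freq=[0.5], seed=1)
        meta = eg.init_metapopulation(cfg, 10_000, n_pops=1)
        dosage = meta.populations[0].genotypes.sum(axis=2)
        ho = (dosage == 1).mean()
        sigma = np.sqrt(0.5 * 0.5 / 10_000)
        assert abs(ho - 0.5) < 3 * sigma

    def test_genotype_spectrum_matches_binomial(self):
        """Counts of dosage 0/1/2 match Binomial(2, p) pooled over 20 seeds."""
        p = 0.3
        counts = np.zeros(3)
        for seed in range(20):
            cfg = eg.DemographyConfig(n_loci=5, init_allele_freq=[p] * 5, seed=seed)
            meta = eg.init_metapopulation(cfg, 200, n_pops=1)
            dosage = meta.populations[0].genotypes.sum(axis=2).ravel()
            counts += np.bincount(dosage, minlength=3)
        expected = counts.sum() * np.array(
            [(1 - p) ** 2, 2 * p * (1 - p), p**2]
        )
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=2)

    def test_near_fixed_frequency_is_monomorphic(self):
        cfg = eg.DemographyConfig(n_loci=3, init_allele_freq=[1 - 1e-12] * 3, seed=2)
        meta = eg.init_metapopulation(cfg, 100, n_pops=1)
        assert (meta.populations[0].genotypes == 1).all()

    def test_initial_ages_follow_geometric_distribution(self):
        cfg = eg.DemographyConfig(seed=3)
        meta = eg.init_metapopulation(cfg, 10_000, n_pops=1)
        ages = meta.populations[0].age
        # geometric(0.2): mean 5, variance 20
        assert abs(ages.mean() - 5.0) < 3 * np.sqrt(20 / 10_000)

    def test_invalid_allele_frequency_rejected(self):
        with pytest.raises(ValueError):
            eg.DemographyConfig(n_loci=2, init_allele_freq=[0.5, 1.0])

    def test_nonpositive_size_rejected(self):
        cfg = eg.DemographyConfig()
        with pytest.raises(ValueError):
            eg.init_metapopulation(cfg, 0, n_pops=2)


class TestMortality:
    def test_death_count_within_binomial_band(self):
        cfg = eg.DemographyConfig(seed=4)
        meta = eg.init_metapopulation(cfg, 900, n_pops=40)
        rng = np.random.default_rng(5)
        deaths = eg.apply_mortality(meta, cfg, rng).sum()
        sigma = np.sqrt(36_000 * 0.2 * 0.8)
        assert abs(deaths - 7200) < 3 * sigma

    def test_zero_mortality_only_ages(self):
        cfg = eg.DemographyConfig(mortality_rate=0.0, seed=6)
        meta = eg.init_metapopulation(cfg, 50, n_pops=2)
        ages_before = [p.age.copy() for p in meta.populations]
        deaths = eg.apply_mortality(meta, cfg, np.random.default_rng(0))
        assert deaths.sum() == 0
        for before, pop in zip(ages_before, meta.populations):
            np.testing.assert_array_equal(pop.age, before + 1)


class TestReproduce:
    def test_mendel_fixed_cross(self):
        """AA x aa parents: every offspring is heterozygous."""
        geno = np.stack([np.ones((1, 5, 2)), np.zeros((1, 5, 2))]).reshape(2, 5, 2)
        pop = make_pop(geno, sexes=[eg.FEMALE, eg.MALE])
        cfg = eg.DemographyConfig(n_loci=5)
        off, sexes, ages = eg.reproduce(pop, 50, cfg, np.random.default_rng(1))
        assert (off.sum(axis=2) == 1).all()
        assert len(sexes) == 50 and len(ages) == 100

    def test_punnett_ratios_het_cross(self):
        """Aa x Aa: offspring dosage follows (1/4, 1/2, 1/4)."""
        het = np.array([[[0, 1]]])
        geno = np.concatenate([het, het])
        pop = make_pop(geno, sexes=[eg.FEMALE, eg.MALE])
        cfg = eg.DemographyConfig(n_loci=1)
        off, _, _ = eg.reproduce(pop, 10_000, cfg, np.random.default_rng(2))
        counts = np.bincount(off.sum(axis=2).ravel(), minlength=3)
        expected = 10_000 * np.array([0.25, 0.5, 0.25])
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=2)

    def test_reproductive_success_is_overdispersed(self):
        """Gamma(0.5) pair weights: among-pair offspring-number variance well
        above the Poisson variance at the same mean."""
        n_pairs, brood = 100, 100
        cfg = eg.DemographyConfig(n_loci=1)
        all_counts = []
        for seed in range(50):
            # unique female ages identify the mother of each offspring
            ages = np.concatenate([np.arange(1, n_pairs + 1), np.arange(1, n_pairs + 1)])
            sexes = [eg.FEMALE] * n_pairs + [eg.MALE] * n_pairs
            geno = np.zeros((2 * n_pairs, 1, 2))
            pop = make_pop(geno, sexes=sexes, ages=ages)
            _, _, par_ages = eg.reproduce(pop, brood, cfg, np.random.default_rng(seed))
            mother_ages = par_ages[:brood]
            counts = np.bincount(mother_ages, minlength=n_pairs + 1)[1:]
            all_counts.append(counts)
        counts = np.concatenate(all_counts)
        assert counts.mean() == pytest.approx(1.0)
        assert counts.var() > 2.0 * counts.mean()  # Poisson would be ~= mean

    def test_single_sex_population_produces_nothing(self, caplog):
        geno = np.zeros((4, 2, 2))
        pop = make_pop(geno, sexes=[eg.MALE] * 4)
        cfg = eg.DemographyConfig(n_loci=2)
        with caplog.at_level("WARNING"):
            off, sexes, ages = eg.reproduce(pop, 10, cfg, np.random.default_rng(3))
        assert len(sexes) == 0
        assert "no mating pairs" in caplog.text

    def test_immature_age_zero_excluded(self):
        geno = np.zeros((4, 1, 2))
        pop = make_pop(geno, sexes=[eg.FEMALE, eg.FEMALE, eg.MALE, eg.MALE],
                       ages=[0, 3, 0, 7])
        cfg = eg.DemographyConfig(n_loci=1)
        _, _, par_ages = eg.reproduce(pop, 20, cfg, np.random.default_rng(4))
        assert set(par_ages.tolist()) == {3, 7}


class TestDisperse:
    def test_identity_matrix_recruits_are_natal(self):
        rng = np.random.default_rng(5)
        counts = eg.disperse_recruits(
            np.full(5, 100), pt.identity_matrix(5), rng
        )
        np.testing.assert_array_equal(counts, np.diag(np.full(5, 100)))

    def test_uniform_matrix_multinomial_moments(self):
        rng = np.random.default_rng(6)
        demand = np.zeros(40, dtype=int)
        demand[7] = 400
        counts = eg.disperse_recruits(demand, pt.uniform_matrix(40), rng)
        col = counts[:, 7]
        assert col.sum() == 400
        sigma = np.sqrt(400 * (1 / 40) * (39 / 40))
        assert (np.abs(col - 10) < 4 * sigma).all()

    def test_two_origin_column_binomial_moments(self):
        P = np.zeros((40, 40))
        P[0, 5] = 0.2
        P[1, 5] = 0.8
        matrix = pt.ConnectivityMatrix(P)
        demand = np.zeros(40, dtype=int)
        demand[5] = 1000
        rng = np.random.default_rng(7)
        counts = eg.disperse_recruits(demand, matrix, rng)
        sigma = np.sqrt(1000 * 0.2 * 0.8)
        assert abs(counts[0, 5] - 200) < 3 * sigma
        assert counts[0, 5] + counts[1, 5] == 1000

    def test_zero_column_yields_no_recruits(self, caplog):
        P = np.zeros((3, 3))
        P[:, :2] = 1 / 3  # column 3 empty
        matrix = pt.ConnectivityMatrix(P)
        with caplog.at_level("WARNING"):
            counts = eg.disperse_recruits(
                np.array([10, 10, 10]), matrix, np.random.default_rng(8)
            )
        assert counts[:, 2].sum() == 0
        assert "zero connectivity" in caplog.text

    def test_recruit_sd_perturbs_totals(self):
        rng = np.random.default_rng(9)
        counts = eg.disperse_recruits(
            np.full(4, 200), pt.uniform_matrix(4), rng, recruit_sd=105.0
        )
        totals = counts.sum(axis=0)
        assert (totals != 200).any()
        assert (totals >= 0).all()


class TestRunSimulation:
    def test_uniform_matrix_is_panmictic(self):
        cfg = eg.DemographyConfig(n_loci=50, model_years=50, seed=10)
        res = eg.run_simulation(pt.uniform_matrix(10), cfg, local_n=150)
        assert abs(np.nanmean(res.fst.lower_triangle())) < 0.005

    def test_drift_ordering_identity_exceeds_uniform(self):
        """Closed populations drift apart; panmixia does not (20 replicates)."""
        fst_identity, fst_uniform = [], []
        for seed in range(20):
            cfg = eg.DemographyConfig(n_loci=30, model_years=40, seed=seed)
            for matrix, out in (
                (pt.identity_matrix(6), fst_identity),
                (pt.uniform_matrix(6), fst_uniform),
            ):
                res = eg.run_simulation(matrix, cfg, local_n=80)
                out.append(np.nanmean(res.fst.lower_triangle()))
        assert np.mean(fst_identity) > np.mean(fst_uniform) + 0.01

    def test_island_model_fst_decreases_with_migration(self):
        """Mean F_ST ordered against Wright's 1/(1 + 4 N m) trend."""
        means = []
        for m in (0.001, 0.01, 0.1):
            vals = []
            for seed in range(8):
                cfg = eg.DemographyConfig(n_loci=30, model_years=60, seed=200 + seed)
                res = eg.run_simulation(pt.island_matrix(5, m), cfg, local_n=150)
                vals.append(np.nanmean(res.fst.lower_triangle()))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_matrix_set_redraws_each_year(self):
        cfg = eg.DemographyConfig(n_loci=10, model_years=15, seed=11)
        res = eg.run_simulation(
            [pt.uniform_matrix(4), pt.identity_matrix(4)], cfg, local_n=60
        )
        assert res.years_run == 15

    def test_order_of_operations(self):
        stages = []
        cfg = eg.DemographyConfig(n_loci=5, model_years=3, seed=12)
        eg.run_simulation(
            pt.uniform_matrix(3), cfg, local_n=40, compute_fst=False,
            year_hook=lambda stage, year, _: stages.append((year, stage)),
        )
        per_year = [s for y, s in stages if y == 1]
        assert per_year == ["mortality", "reproduction", "dispersal", "recruitment"]

    def test_size_regulation_near_capacity(self):
        """Long-run metapopulation size stays within 5% of the configured
        40,000 capacity (40 populations at the 1000-per-population setting;
        the recruit-demand deviate's SD of 105 is absolute, so the check
        belongs at this scale)."""
        cfg = eg.DemographyConfig(n_loci=10, model_years=60, seed=13)
        res = eg.run_simulation(
            pt.uniform_matrix(40), cfg, local_n=1000, compute_fst=False
        )
        long_run = res.pop_sizes_by_year[20:].sum(axis=1).mean()
        assert long_run == pytest.approx(40_000, rel=0.05)

    def test_neutrality_no_systematic_drift_bias(self):
        """Across replicates the grand mean allele frequency stays at its
        initial value (the model adds no directional force)."""
        finals = []
        for seed in range(50):
            cfg = eg.DemographyConfig(
                n_loci=20, init_allele_freq=[0.5] * 20, model_years=30, seed=seed
            )
            res = eg.run_simulation(
                pt.uniform_matrix(4), cfg, local_n=50, compute_fst=False
            )
            finals.append(res.metapopulation.allele_frequencies().mean())
        finals = np.asarray(finals)
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - 0.5) < 3 * se

    def test_no_recruitment_leads_to_extinction(self):
        cfg = eg.DemographyConfig(mortality_rate=0.5, n_loci=5, model_years=60, seed=14)
        res = eg.run_simulation(
            pt.ConnectivityMatrix(np.zeros((3, 3))), cfg, local_n=20,
            compute_fst=False,
        )
        assert res.extinct
        assert res.years_run < 60

    def test_identical_seed_identical_result(self):
        cfg = eg.DemographyConfig(n_loci=10, model_years=10, seed=15)
        r1 = eg.run_simulation(pt.uniform_matrix(4), cfg, local_n=50)
        r2 = eg.run_simulation(pt.uniform_matrix(4), cfg, local_n=50)
        np.testing.assert_array_equal(r1.pop_sizes_by_year, r2.pop_sizes_by_year)
        np.testing.assert_array_equal(r1.fst.values, r2.fst.values)


class TestGenerationTime:
    def test_forced_parental_age(self):
        res = eg.SimulationResult(
            metapopulation=None, pop_sizes_by_year=np.zeros((4, 1)),
            parental_age_sum=np.array([0.0, 30.0, 60.0, 90.0]),
            parental_age_count=np.array([0.0, 10.0, 20.0, 30.0]),
            fst=None, config=eg.DemographyConfig(), seed=0, years_run=4,
        )
        assert eg.mean_generation_time(res, burn_in=1) == 3.0

    def test_higher_mortality_shortens_generations(self):
        gts = []
        for mortality in (0.2, 0.5):
            cfg = eg.DemographyConfig(
                mortality_rate=mortality, n_loci=5, model_years=40, seed=16
            )
            res = eg.run_simulation(
                pt.uniform_matrix(8), cfg, local_n=300, compute_fst=False
            )
            gts.append(eg.mean_generation_time(res, burn_in=15))
        assert gts[1] < gts[0]

    def test_no_records_after_burn_in_rejected(self):
        res = eg.SimulationResult(
            metapopulation=None, pop_sizes_by_year=np.zeros((2, 1)),
            parental_age_sum=np.zeros(2), parental_age_count=np.zeros(2),
            fst=None, config=eg.DemographyConfig(), seed=0, years_run=2,
        )
        with pytest.raises(ValueError):
            eg.mean_generation_time(res, burn_in=0)


def test_drift_calibration_heterozygosity_decay():
    """Under a fully retentive matrix, expected heterozygosity decays like
    (1 - 1/(2 N_e))^generations.  Sweepstakes reproduction (gamma 0.5 pair
    weights) depresses N_e below census size, and the decay-estimated N_e
    scales proportionally with census size within a factor-2 band."""

    def estimate_ne(local_n, seeds):
        ne_hats = []
        for seed in seeds:
            cfg = eg.DemographyConfig(
                n_loci=100, init_allele_freq=[0.5] * 100, model_years=60, seed=seed
            )
            res = eg.run_simulation(
                pt.identity_matrix(4), cfg, local_n=local_n, compute_fst=False
            )
            gens = 60.0 / eg.mean_generation_time(res, burn_in=10)
            for pop in res.metapopulation.populations:
                p = pop.genotypes.sum(axis=(0, 2)) / (2.0 * pop.size)
                he = np.mean(2.0 * p * (1.0 - p))
                ne_hats.append(-1.0 / (2.0 * np.log(he / 0.5) / gens))
        return np.mean(ne_hats)

    ne_100 = estimate_ne(100, range(4))
    ne_200 = estimate_ne(200, range(4, 8))
    assert ne_100 < 100 and ne_200 < 200  # reproductive skew lowers N_e
    assert 0.5 < (ne_200 / ne_100) / 2.0 < 2.0  # proportional to census N


def test_metapopulation_genotype_table_round_trip():
    cfg = eg.DemographyConfig(n_loci=8, seed=17)
    meta = eg.init_metapopulation(cfg, [30, 40], n_pops=None)
    table = meta.to_genotype_table()
    assert table.n_individuals == 70
    assert table.site_labels == ["SITE_1", "SITE_2"]
    np.testing.assert_array_equal(
        table.dosage[:30], meta.populations[0].genotypes.sum(axis=2)
    )
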