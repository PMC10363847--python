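import numpy as np
import pytest

from ecoconnect import synthetic_domain as sd
from ecoconnect.popgen import GenotypeTable


@pytest.fixture(scope="session")
def partition20():
    return sd.build_region_partition(20)


@pytest.fixture(scope="session")
def partition4():
    return sd.build_region_partition(4)


@pytest.fixture()
def toy_two_site_table():
    """The hand-oracle fixture: site A = 4 AA + 6 Aa, site B = 1 AA + 4 Aa + 5 aa.

    Coded as alternate-allele dosage with 'A' as the alternate allele; the
    Weir-Cockerham estimator is invariant to which allele is labeled
    alternate.
    """
    dosage = np.array([2] * 4 + [1] * 6 + [2] * 1 + [1] * 4 + [0] * 5)[:, None]
    sites = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
    return GenotypeTable(dosage, sites, ["L1"])


def hwe_table(p, n_per_site, site_names, n_loci, seed):
    """Genotypes drawn from one HWE pool shared by all sites."""
    rng = np.random.default_rng(seed)
    n = n_per_site * len(site_names)
    dosage = rng.binomial(2, p, size=(n, n_loci)).astype(np.int8)
    sites = np.repeat(np.asarray(site_names, dtype=object), n_per_site)
    return GenotypeTable(dosage, sites, [f"L{j}" for j in range(n_loci)])
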