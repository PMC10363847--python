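"""Genotype-matrix statistics shared by simulated and empirical data.

The central quantity is pairwise Weir & Cockerham (1984) theta, the
variance-components ("unbiased") estimator of F_ST.  For two populations and
one biallelic locus the estimator partitions allelic variance into
among-population (a), among-individual-within-population (b) and
within-individual (c) components; the multilocus estimate is the
ratio-of-sums  theta = sum_l a_l / sum_l (a_l + b_l + c_l),  never the mean
of per-locus ratios.  Small negative estimates are meaningful (sampling noise
around zero differentiation) and are retained.

Genotypes are held as an individuals x loci dosage matrix (count of the
alternate allele, 0/1/2, -1 for missing) with a population ("site") label per
individual.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_SAMPLE_SITE_RE = re.compile(r"^(?P<site>.+)_\d+$")


@dataclass
class GenotypeTable:
    """Diploid biallelic genotypes for a set of individuals at shared loci.

    Attributes
    ----------
    dosage : (n_individuals, n_loci) int8 array
        Count of the alternate allele per call; ``-1`` marks a missing call.
    sites : (n_individuals,) array of str
        Population label of each individual.
    loci : list of str
        Locus identifiers, one per column.
    sample_ids : list of str
        Per-individual identifiers (generated when not supplied).
    """

    dosage: np.ndarray
    sites: np.ndarray
    loci: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x loci)")
        self.sites = np.asarray(self.sites, dtype=object)
        if self.sites.shape[0] != self.dosage.shape[0]:
            raise ValueError("one site label per individual required")
        if len(self.loci) != self.dosage.shape[1]:
            raise ValueError("one locus ID per dosage column required")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or -1 (missing)")
        if not self.sample_ids:
            counters: dict[str, int] = {}
            ids = []
            for s in self.sites:
                counters[s] = counters.get(s, 0) + 1
                ids.append(f"{s}_{counters[s]:03d}")
            self.sample_ids = ids

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def site_labels(self) -> list[str]:
        """Unique site labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s, None)
        return list(seen)

    def restrict_sites(self, keep: list[str]) -> "GenotypeTable":
        mask = np.isin(self.sites, keep)
        return GenotypeTable(
            self.dosage[mask],
            self.sites[mask],
            list(self.loci),
            [sid for sid, m in zip(self.sample_ids, mask) if m],
        )


@dataclass
class FstMatrix:
    """Symmetric matrix of multilocus pairwise Weir-Cockerham theta.

    The diagonal is zero; entries for pairs with no usable loci are NaN.
    """

    values: np.ndarray
    sites: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        s = len(self.sites)
        if self.values.shape != (s, s):
            raise ValueError("FstMatrix shape must match number of sites")

    def lower_triangle(self) -> np.ndarray:
        """Pairwise values vectorized in (row, col) lower-triangle order."""
        idx = np.tril_indices(len(self.sites), k=-1)
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sites, columns=self.sites)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.10g")

    @classmethod
    def read(cls, path: str | Path) -> "FstMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("F_ST matrix file must have matching row/column labels")
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])


def infer_site_labels(sample_ids: list[str]) -> np.ndarray:
    """Derive site labels from sample IDs of the form ``<site>_<number>``.

    IDs that do not match the pattern become their own singleton site.
    """
    labels = []
    for sid in sample_ids:
        m = _SAMPLE_SITE_RE.match(sid)
        labels.append(m.group("site") if m else sid)
    return np.asarray(labels, dtype=object)


def read_vcf(path: str | Path) -> GenotypeTable:
    """Read biallelic SNP genotypes from a VCF into a :class:`GenotypeTable`.

    Multiallelic records are skipped (the skip count is recorded on the
    returned table as ``table.n_skipped_multiallelic``).  Missing genotypes
    are preserved as missing.  Site labels are inferred from sample-ID
    prefixes (``SITE_<region>_<nnn>``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    loci: list[str] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(variant.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING  # gts012: 3 encodes unknown
        rows.append(gt)
        loci.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    vcf.close()
    dosage = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    table = GenotypeTable(dosage, infer_site_labels(samples), loci, samples)
    table.n_skipped_multiallelic = n_skipped  # type: ignore[attr-defined]
    return table


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write a GT-only VCF v4.2; dosage/site labels/locus order round-trip."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ecoconnect\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        for j, locus in enumerate(table.loci):
            calls = "\t".join(_GT_STRINGS[int(d)] for d in table.dosage[:, j])
            fh.write(f"1\t{j + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def write_genepop(table: GenotypeTable, path: str | Path, title: str = "ecoconnect") -> None:
    """Export genotypes in Genepop format (2-digit allele coding)."""
    code = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        for site in table.site_labels:
            fh.write("POP\n")
            for i in np.flatnonzero(table.sites == site):
                genos = " ".join(code[int(d)] for d in table.dosage[i])
                fh.write(f"{table.sample_ids[i]}, {genos}\n")


def _site_locus_summaries(table: GenotypeTable):
    """Per-site, per-locus genotyped counts, alt-allele frequency, het fraction."""
    sites = table.site_labels
    d = table.dosage
    called = d != MISSING
    n = np.zeros((len(sites), table.n_loci))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for k, s in enumerate(sites):
        rows = table.sites == s
        dk = d[rows]
        ck = called[rows]
        nk = ck.sum(axis=0)
        n[k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(ck, dk, 0).sum(axis=0) / (2.0 * nk)
            h[k] = (dk == 1).sum(axis=0) / nk
    return sites, n, p, h


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) a, b, c variance components for two populations.

    Inputs are per-locus arrays of sample sizes (individuals), alternate-allele
    frequencies and observed heterozygote fractions.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    pq = pbar * (1.0 - pbar)
    inner = pq - (r - 1.0) / r * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(table: GenotypeTable) -> FstMatrix:
    """Multilocus pairwise Weir-Cockerham theta among all sites.

    For each pair of sites, a locus enters the sums only when both sites have
    at least two genotyped individuals there (pairwise-complete rule); loci
    monomorphic across the pair contribute zero to numerator and denominator.
    A pair with no informative locus at all is NaN.
    """
    sites, n, p, h = _site_locus_summaries(table)
    s = len(sites)
    if s < 2:
        raise ValueError("pairwise F_ST requires at least two sites")
    out = np.zeros((s, s))
    for i in range(s):
        for j in range(i):
            usable = (n[i] >= 2) & (n[j] >= 2)
            if not usable.any():
                out[i, j] = out[j, i] = np.nan
                continue
            a, b, c = _wc_components(
                n[i][usable], p[i][usable], h[i][usable],
                n[j][usable], p[j][usable], h[j][usable],
            )
            denom = (a + b + c).sum()
            theta = a.sum() / denom if denom != 0.0 else np.nan
            out[i, j] = out[j, i] = theta
    return FstMatrix(out, sites)


@dataclass
class HeterozygosityResult:
    """Observed and expected heterozygosity, per site and pooled."""

    per_site: pd.DataFrame  # columns: H_o, H_e, n
    global_ho: float
    global_he: float


def heterozygosity(table: GenotypeTable) -> HeterozygosityResult:
    """H_o (fraction of heterozygous calls) and unbiased H_e per site.

    H_e uses Nei's unbiased small-sample correction ``2n/(2n-1) * 2p(1-p)``
    averaged over loci with at least one genotyped individual.
    """
    if table.n_individuals == 0 or table.n_loci == 0:
        raise ValueError("heterozygosity requires a non-empty genotype table")
    sites, n, p, h = _site_locus_summaries(table)
    records = {}
    for k, s in enumerate(sites):
        ok = n[k] >= 1
        ho = float(h[k][ok].mean()) if ok.any() else np.nan
        corr = 2.0 * n[k][ok] / (2.0 * n[k][ok] - 1.0) if ok.any() else np.nan
        he = float((corr * 2.0 * p[k][ok] * (1.0 - p[k][ok])).mean()) if ok.any() else np.nan
        records[s] = {"H_o": ho, "H_e": he, "n": int((table.sites == s).sum())}
    per_site = pd.DataFrame.from_dict(records, orient="index")

    called = table.dosage != MISSING
    nk = called.sum(axis=0).astype(float)
    ok = nk >= 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pg = np.where(called, table.dosage, 0).sum(axis=0) / (2.0 * nk)
        hg = (table.dosage == 1).sum(axis=0) / nk
    corr = 2.0 * nk[ok] / (2.0 * nk[ok] - 1.0)
    return HeterozygosityResult(
        per_site=per_site,
        global_ho=float(hg[ok].mean()),
        global_he=float((corr * 2.0 * pg[ok] * (1.0 - pg[ok])).mean()),
    )
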