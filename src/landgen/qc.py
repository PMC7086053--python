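"""Genotype input and post-variant-calling SNP quality control.

The filter chain mirrors standard reduced-representation practice for a
polyploid-prone conifer dataset: drop non-biallelic records, remove putative
homeologs by excess observed heterozygosity (> 0.70), remove SNPs with > 50%
missing calls, remove minor allele frequency < 0.05 (pooled over all
individuals), and optionally thin to one SNP per GBS fragment.  Filters are
applied in the fixed order biallelic -> heterozygosity -> missingness -> MAF
so that per-rule removal accounting is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "FilterReport",
    "AlleleFreqMatrix",
    "read_genotypes",
    "filter_variants",
    "thin_one_per_fragment",
    "population_frequencies",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs alternate-allele counts; -1 encodes a missing call.

    Positions are 1-based (VCF convention).  ``n_alleles`` counts REF+ALT
    alleles of the source record; records with more than 2 are retained at
    read time and removed by the biallelic filter.
    """

    genotypes: np.ndarray          # (n_ind, n_snp) int8
    samples: np.ndarray            # (n_ind,) str
    populations: np.ndarray        # (n_ind,) str, one population per sample
    snp_ids: np.ndarray            # (n_snp,) str
    fragments: np.ndarray          # (n_snp,) str
    positions: np.ndarray          # (n_snp,) int, 1-based
    ref: np.ndarray
    alt: np.ndarray
    n_alleles: np.ndarray          # (n_snp,) int

    def __post_init__(self):
        if self.genotypes.shape != (len(self.samples), len(self.snp_ids)):
            raise ValueError("genotype matrix shape does not match metadata")
        if np.any(self.positions < 0):
            raise ValueError("positions must be non-negative")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def pop_names(self) -> list[str]:
        return list(dict.fromkeys(self.populations.tolist()))

    def take_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, idx],
            samples=self.samples, populations=self.populations,
            snp_ids=self.snp_ids[idx], fragments=self.fragments[idx],
            positions=self.positions[idx], ref=self.ref[idx],
            alt=self.alt[idx], n_alleles=self.n_alleles[idx])

    # --- per-SNP summaries used by several modules -----------------------
    def missing_fraction(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def het_fraction(self) -> np.ndarray:
        """Observed heterozygote fraction among non-missing genotypes."""
        called = self.genotypes != MISSING
        n = called.sum(axis=0)
        het = (self.genotypes == 1).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, het / np.maximum(n, 1), np.nan)

    def pooled_maf(self) -> np.ndarray:
        called = self.genotypes != MISSING
        alleles = 2 * called.sum(axis=0)
        alt = np.where(called, self.genotypes, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(alleles > 0, alt / np.maximum(alleles, 1), np.nan)
        return np.minimum(p, 1.0 - p)


@dataclass
class FilterReport:
    """Per-rule accounting of the filter chain: counts and removed SNP IDs."""

    n_input: int
    rules: list[str] = field(default_factory=list)
    removed: dict[str, list[str]] = field(default_factory=dict)
    n_after: dict[str, int] = field(default_factory=dict)

    @property
    def n_output(self) -> int:
        return self.n_after[self.rules[-1]] if self.rules else self.n_input

    def record(self, rule: str, removed_ids, n_after: int) -> None:
        self.rules.append(rule)
        self.removed[rule] = list(removed_ids)
        self.n_after[rule] = n_after

    def to_frame(self) -> pd.DataFrame:
        rows, before = [], self.n_input
        for r in self.rules:
            rows.append({"rule": r, "n_before": before,
                         "n_removed": len(self.removed[r]),
                         "n_after": self.n_after[r]})
            before = self.n_after[r]
        return pd.DataFrame(rows)


@dataclass
class AlleleFreqMatrix:
    """Populations x SNPs alternate-allele frequency plus allele counts.

    ``freq`` is NaN where a population has no genotyped individual at a SNP;
    ``counts`` holds the number of non-missing allele copies (2 x genotyped
    individuals) behind each frequency.
    """

    freq: np.ndarray               # (n_pop, n_snp) float, NaN = undefined
    counts: np.ndarray             # (n_pop, n_snp) int
    populations: list[str]
    snp_ids: np.ndarray

    def __post_init__(self):
        defined = ~np.isnan(self.freq)
        if np.any((self.freq[defined] < 0) | (self.freq[defined] > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if np.any((self.counts == 0) & defined):
            raise ValueError("frequency defined where allele count is zero")

    @property
    def n_pops(self) -> int:
        return self.freq.shape[0]

    @property
    def n_snps(self) -> int:
        return self.freq.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, columns=self.snp_ids)
        df.insert(0, "population", self.populations)
        return df

    def take_snps(self, idx) -> "AlleleFreqMatrix":
        idx = np.asarray(idx)
        return AlleleFreqMatrix(self.freq[:, idx], self.counts[:, idx],
                                self.populations, self.snp_ids[idx])


def read_genotypes(vcf_path, popmap_path) -> GenotypeMatrix:
    """Read GT fields from a VCF plus a sample->population map (TSV, no header).

    Half-calls (one missing allele) and non-diploid genotypes raise; records
    with more than one ALT allele are retained and flagged for the biallelic
    filter.  Every VCF sample must appear in the popmap.
    """
    from cyvcf2 import VCF

    popmap = pd.read_csv(popmap_path, sep="\t", header=None,
                         names=["sample", "population"], dtype=str)
    pop_of = dict(zip(popmap["sample"], popmap["population"]))

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in pop_of:
            raise KeyError(f"sample {s!r} present in VCF but absent from popmap")

    rows, ids, frags, poss, refs, alts, nall = [], [], [], [], [], [], []
    for i, var in enumerate(vcf):
        gts = var.genotypes
        col = np.empty(len(samples), dtype=np.int8)
        for j, gt in enumerate(gts):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid genotype at {var.CHROM}:{var.POS} sample {samples[j]}")
            a, b = alleles
            if a < 0 and b < 0:
                col[j] = MISSING
            elif a < 0 or b < 0:
                raise ValueError(
                    f"half-call at {var.CHROM}:{var.POS} sample {samples[j]}")
            else:
                col[j] = (a > 0) + (b > 0)  # count of non-REF alleles
        rows.append(col)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        frag = dict(var.INFO).get("FRAG", var.CHROM)
        frags.append(frag)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(",".join(var.ALT) if var.ALT else ".")
        nall.append(1 + len(var.ALT))

    geno = np.array(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(
        genotypes=geno,
        samples=np.array(samples),
        populations=np.array([pop_of[s] for s in samples]),
        snp_ids=np.array(ids), fragments=np.array(frags),
        positions=np.array(poss, dtype=np.int64),
        ref=np.array(refs), alt=np.array(alts),
        n_alleles=np.array(nall, dtype=np.int64))


def filter_variants(g: GenotypeMatrix, het_max: float = 0.70,
                    miss_max: float = 0.50, maf_min: float = 0.05,
                    biallelic_only: bool = True):
    """Apply the SNP filter chain; returns (filtered matrix, FilterReport).

    Rules, in order: keep exactly-biallelic records; drop SNPs whose observed
    heterozygote fraction (among called genotypes) exceeds ``het_max``
    (homeolog screen); drop SNPs with missing fraction above ``miss_max``;
    drop SNPs whose pooled minor allele frequency falls below ``maf_min``.
    """
    for t, name in ((het_max, "het_max"), (miss_max, "miss_max"), (maf_min, "maf_min")):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    report = FilterReport(n_input=g.n_snps)
    cur = g

    def apply(rule, keep_mask):
        nonlocal cur
        removed = cur.snp_ids[~keep_mask]
        cur = cur.take_snps(np.flatnonzero(keep_mask))
        report.record(rule, removed, cur.n_snps)

    if biallelic_only:
        apply("biallelic", cur.n_alleles == 2)
    with np.errstate(invalid="ignore"):
        het = cur.het_fraction()
    apply("heterozygosity", ~(het > het_max))          # NaN (all-missing) passes
    apply("missingness", cur.missing_fraction() <= miss_max)
    maf = cur.pooled_maf()
    apply("maf", ~(maf < maf_min))                     # NaN passes only if maf_min == 0
    if maf_min > 0:
        cur_maf = cur.pooled_maf()
        keep = ~np.isnan(cur_maf)
        if not keep.all():
            idx = np.flatnonzero(keep)
            report.removed["maf"].extend(cur.snp_ids[~keep])
            cur = cur.take_snps(idx)
            report.n_after["maf"] = cur.n_snps
    if cur.n_snps == 0:
        warnings.warn("no SNPs survive the filter chain", stacklevel=2)
    return cur, report


def thin_one_per_fragment(g: GenotypeMatrix) -> GenotypeMatrix:
    """Keep one SNP per fragment: lowest position, ties by SNP ID."""
    order = np.lexsort((g.snp_ids, g.positions, g.fragments))
    seen, keep = set(), []
    for i in order:
        f = g.fragments[i]
        if f not in seen:
            seen.add(f)
            keep.append(i)
    return g.take_snps(np.sort(np.array(keep, dtype=int)))


def population_frequencies(g: GenotypeMatrix,
                           min_poly_pops: int = 0) -> AlleleFreqMatrix:
    """Per-population alternate-allele frequencies with allele counts.

    Frequency = alt-allele count / non-missing allele count within the
    population; undefined (NaN) where no individual is genotyped.  When
    ``min_poly_pops`` > 0, SNPs polymorphic (0 < p < 1) in fewer than that
    many populations are dropped.
    """
    pops = g.pop_names
    n_pop, n_snp = len(pops), g.n_snps
    freq = np.full((n_pop, n_snp), np.nan)
    counts = np.zeros((n_pop, n_snp), dtype=np.int64)
    for k, pop in enumerate(pops):
        sub = g.genotypes[g.populations == pop]
        called = sub != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        counts[k] = n_alleles
        nz = n_alleles > 0
        freq[k, nz] = alt[nz] / n_alleles[nz]
    out = AlleleFreqMatrix(freq, counts, pops, g.snp_ids.copy())
    if min_poly_pops > 0:
        poly = np.nansum((out.freq > 0) & (out.freq < 1), axis=0)
        out = out.take_snps(np.flatnonzero(poly >= min_poly_pops))
    return out
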