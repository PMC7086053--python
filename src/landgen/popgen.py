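"""Per-population diversity and Weir-Cockerham differentiation.

Diversity statistics are computed per population over retained variant
sites: observed heterozygosity (Hobs), per-site nucleotide diversity
``pi = (2n/(2n-1)) * 2*p*(1-p)`` averaged over sites (n = genotyped
individuals at the site), and Wright's inbreeding coefficient
``FIS = 1 - mean(Hobs)/mean(He)`` with Nei's unbiased expected
heterozygosity, aggregated as a ratio of multi-locus averages.

Differentiation uses the Weir-Cockerham (1984) moment estimator: per-locus
variance components a (among populations), b (among individuals within
populations) and c (within individuals), combined multi-locus as
``theta = sum(a) / sum(a + b + c)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .qc import MISSING, GenotypeMatrix

__all__ = [
    "diversity_per_population",
    "weir_cockerham_components",
    "weir_cockerham_theta",
    "pairwise_fst",
    "linearize_fst",
]


def diversity_per_population(g: GenotypeMatrix) -> pd.DataFrame:
    """Table of per-population N, Hobs, pi, and FIS.

    SNPs with no genotyped individual in a population are skipped for that
    population.  If expected heterozygosity is zero at every locus
    (monomorphic-only input) FIS is undefined and reported as NaN.
    """
    rows = []
    for pop in g.pop_names:
        sub = g.genotypes[g.populations == pop]
        called = sub != MISSING
        n = called.sum(axis=0)                        # genotyped individuals
        ok = n > 0
        het = (sub == 1).sum(axis=0)
        hobs_l = het[ok] / n[ok]
        alt = np.where(called, sub, 0).sum(axis=0)
        p = alt[ok] / (2 * n[ok])
        two_n = 2 * n[ok]
        with np.errstate(invalid="ignore", divide="ignore"):
            he_l = np.where(two_n > 1, two_n / (two_n - 1) * 2 * p * (1 - p), np.nan)
        pi = float(np.nanmean(he_l)) if ok.any() else np.nan
        hobs = float(hobs_l.mean()) if ok.any() else np.nan
        mean_he = float(np.nanmean(he_l)) if ok.any() else np.nan
        fis = 1.0 - hobs / mean_he if mean_he and mean_he > 0 else np.nan
        rows.append({"population": pop, "n": int(sub.shape[0]),
                     "hobs": hobs, "pi": pi, "fis": fis})
    return pd.DataFrame(rows)


def _per_pop_summaries(g: GenotypeMatrix, groups: np.ndarray, labels):
    """Per (group, locus): sample size, alt frequency, observed het fraction."""
    n = np.zeros((len(labels), g.n_snps))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for k, lab in enumerate(labels):
        sub = g.genotypes[groups == lab]
        called = sub != MISSING
        nk = called.sum(axis=0)
        n[k] = nk
        with np.errstate(invalid="ignore"):
            p[k] = np.where(nk > 0, np.where(called, sub, 0).sum(axis=0) / (2 * np.maximum(nk, 1)), np.nan)
            h[k] = np.where(nk > 0, (sub == 1).sum(axis=0) / np.maximum(nk, 1), np.nan)
    return n, p, h


def weir_cockerham_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Variance components (a, b, c) per locus for r groups.

    ``n``, ``p``, ``h`` are (r, L) arrays of per-group genotyped counts,
    alternate-allele frequencies and observed heterozygote fractions.  Loci
    where any group has n < 1, or where nbar <= 1, are returned as NaN.
    """
    r = n.shape[0]
    valid = (n >= 1).all(axis=0)
    nbar = n.mean(axis=0)
    valid &= nbar > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    # nc == 0 happens only when all samples sit in one group
    bad = ~valid | ~np.isfinite(a)
    a, b, c = (np.where(bad, np.nan, x) for x in (a, b, c))
    return a, b, c


def weir_cockerham_theta(g: GenotypeMatrix, groups: np.ndarray | None = None) -> float:
    """Multi-locus theta over the given grouping (default: populations)."""
    groups = g.populations if groups is None else np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("theta requires at least two groups")
    for lab in labels:
        counts = (g.genotypes[groups == lab] != MISSING).sum(axis=0)
        if counts.max(initial=0) < 2:
            raise ValueError(
                f"population {lab!r} has fewer than 2 genotyped individuals at every locus")
    n, p, h = _per_pop_summaries(g, groups, labels)
    a, b, c = weir_cockerham_components(n, p, h)
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    if den == 0:
        return np.nan
    return float(num / den)


def pairwise_fst(g: GenotypeMatrix, groups: np.ndarray | None = None) -> pd.DataFrame:
    """Symmetric matrix of pairwise multi-locus Weir-Cockerham theta."""
    groups = g.populations if groups is None else np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two populations")
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mask = (groups == labels[i]) | (groups == labels[j])
            sub = GenotypeMatrix(
                genotypes=g.genotypes[mask], samples=g.samples[mask],
                populations=groups[mask], snp_ids=g.snp_ids,
                fragments=g.fragments, positions=g.positions,
                ref=g.ref, alt=g.alt, n_alleles=g.n_alleles)
            out[i, j] = out[j, i] = weir_cockerham_theta(sub, groups[mask])
    return pd.DataFrame(out, index=labels, columns=labels)


def linearize_fst(fst: pd.DataFrame) -> pd.DataFrame:
    """Rousset linearization x/(1-x); negative estimates clamped to 0 first."""
    x = fst.to_numpy(float).copy()
    if np.any(x >= 1):
        raise ValueError("FST of 1 cannot be linearized (division by zero)")
    x = np.clip(x, 0.0, None)
    return pd.DataFrame(x / (1.0 - x), index=fst.index, columns=fst.columns)
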