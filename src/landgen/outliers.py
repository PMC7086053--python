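"""Genotype-environment and differentiation outlier scans.

Two complementary scans:

* :func:`pc_mahalanobis_scan` — a principal-component differentiation scan:
  each SNP is regressed on the first K genotype PCs, the K z-scores are
  combined into a robust Mahalanobis distance, rescaled by the genomic
  inflation factor, converted to chi-square p-values and Benjamini-Hochberg
  q-values.
* :func:`env_correlation_scan` — an environmental association scan on
  population allele frequencies: frequencies (and the environmental
  variable) are whitened by the inverse Cholesky factor of the neutral
  population covariance, so shared drift/structure does not masquerade as an
  environmental signal; SNPs in the top fraction of |Spearman rho| are
  flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ordination import _imputed_scaled, genotype_pca
from .qc import AlleleFreqMatrix, GenotypeMatrix

__all__ = [
    "OutlierResult",
    "PopCovariance",
    "pc_mahalanobis_scan",
    "estimate_pop_covariance",
    "env_correlation_scan",
]


@dataclass
class OutlierResult:
    table: pd.DataFrame                # per-SNP statistics and flags
    params: dict

    @property
    def outliers(self) -> np.ndarray:
        return self.table.loc[self.table["outlier"], "snp"].to_numpy()


@dataclass
class PopCovariance:
    """Covariance of standardized population allele frequencies.

    Estimated from a designated neutral SNP set; ridge-regularized to be
    positive definite so the Cholesky factor always exists.
    """

    cov: np.ndarray
    populations: list[str]
    n_snps: int
    ridge: float = 0.0

    @property
    def chol(self) -> np.ndarray:
        return np.linalg.cholesky(self.cov)


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    out = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def pc_mahalanobis_scan(g: GenotypeMatrix, k: int, fdr: float = 0.01,
                        seed: int = 0) -> OutlierResult:
    """PC-based outlier scan with robust Mahalanobis distances.

    Per SNP: regress the scaled genotype column on the first ``k`` PC score
    vectors, keep the K z-scores; D^2 is the Mahalanobis distance of the
    z-vector under a minimum-covariance-determinant estimate; D^2 is divided
    by the genomic inflation factor ``lambda = median(D^2)/median(chi2_K)``
    and referred to the chi-square(K) distribution; q-values by
    Benjamini-Hochberg; SNPs with q <= ``fdr`` are flagged.
    """
    from sklearn.covariance import MinCovDet

    if not 1 <= k < g.n_individuals:
        raise ValueError("K must satisfy 1 <= K < number of individuals")
    x, kept = _imputed_scaled(g)
    if kept.size < g.n_snps:
        warnings.warn(f"{g.n_snps - kept.size} zero-variance SNPs skipped",
                      stacklevel=2)
    pcs = genotype_pca(g).scores[:, :k]              # centered scores
    n = x.shape[0]
    # least-squares z-scores of each SNP column on the K score vectors
    q_mat, r_mat = np.linalg.qr(pcs)
    beta = np.linalg.solve(r_mat, q_mat.T @ x)       # (k, n_kept)
    resid = x - pcs @ beta
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv_diag = np.diag(np.linalg.inv(r_mat.T @ r_mat))
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(xtx_inv_diag, sigma2))
        z = (beta / se).T                            # (n_kept, k)
    z = np.where(np.isfinite(z), z, 0.0)

    mcd = MinCovDet(random_state=seed).fit(z)
    d2 = mcd.mahalanobis(z)
    lam = float(np.median(d2) / stats.chi2.median(df=k))
    p = stats.chi2.sf(d2 / lam, df=k)
    q = _bh_qvalues(p)

    table = pd.DataFrame({"snp": g.snp_ids[kept], "d2": d2,
                          "p_value": p, "q_value": q,
                          "outlier": q <= fdr})
    dropped = np.setdiff1d(np.arange(g.n_snps), kept)
    if dropped.size:
        extra = pd.DataFrame({"snp": g.snp_ids[dropped],
                              "d2": np.nan, "p_value": np.nan,
                              "q_value": np.nan, "outlier": False})
        table = pd.concat([table, extra], ignore_index=True)
    return OutlierResult(table=table,
                         params={"k": k, "fdr": fdr, "lambda": lam, "seed": seed})


def estimate_pop_covariance(freqs: AlleleFreqMatrix,
                            ridge: float = 1e-6) -> PopCovariance:
    """Empirical covariance of standardized population frequency vectors.

    SNP *l* is standardized as ``(p_kl - pbar_l) / sqrt(pbar_l (1 - pbar_l))``
    with ``pbar_l`` the unweighted mean across populations; the covariance is
    taken across SNPs.  A ridge is added if the smallest eigenvalue is not
    positive.
    """
    if freqs.n_pops < 2:
        raise ValueError("covariance needs at least 2 populations")
    if freqs.n_snps < 50:
        warnings.warn("fewer than 50 neutral SNPs: covariance estimate will "
                      "be noisy", stacklevel=2)
    p = freqs.freq
    keep = ~np.isnan(p).any(axis=0)
    p = p[:, keep]
    pbar = p.mean(axis=0)
    poly = (pbar > 0) & (pbar < 1)
    p = p[:, poly]
    pbar = pbar[poly]
    x = (p - pbar) / np.sqrt(pbar * (1 - pbar))
    L = x.shape[1]
    if L < 2:
        raise ValueError("not enough polymorphic SNPs to estimate covariance")
    cov = x @ x.T / (L - 1)
    used_ridge = 0.0
    w = np.linalg.eigvalsh(cov)
    while w.min() <= 0:
        cov = cov + ridge * np.eye(cov.shape[0])
        used_ridge += ridge
        w = np.linalg.eigvalsh(cov)
    return PopCovariance(cov=cov, populations=list(freqs.populations),
                         n_snps=L, ridge=used_ridge)


def _whiten(chol_inv: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Center across populations, then apply the inverse Cholesky factor."""
    return chol_inv @ (v - v.mean())


def env_correlation_scan(freqs: AlleleFreqMatrix, cov: PopCovariance,
                         env: pd.DataFrame,
                         variables: list[str] | None = None,
                         top_fraction: float = 0.05,
                         n_perm: int = 0, seed: int = 0) -> OutlierResult:
    """Covariance-standardized environmental rank-correlation scan.

    Each SNP's population-frequency vector and each (standardized)
    environmental variable are whitened by the inverse Cholesky factor of the
    neutral covariance; the statistic is the Spearman correlation of the two
    whitened vectors.  The top ``top_fraction`` of SNPs by max |rho| across
    variables are flagged.  When ``n_perm`` > 0, a per-SNP permutation
    p-value is attached (population labels of the whitened environment
    permuted).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    if list(freqs.populations) != list(cov.populations):
        raise ValueError("frequency matrix and covariance populations differ")
    variables = variables or [c for c in env.columns if c != "population"]
    e = env.set_index("population").loc[list(freqs.populations), variables]
    x = e.to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = variables[int(np.argmax(sd == 0))]
        raise ValueError(f"environmental variable {bad!r} is constant")
    x = (x - x.mean(axis=0)) / sd

    chol_inv = np.linalg.inv(cov.chol)
    wx = np.column_stack([_whiten(chol_inv, x[:, j]) for j in range(x.shape[1])])

    p = freqs.freq
    mean_p = np.nanmean(p, axis=1)
    rho = np.full((freqs.n_snps, len(variables)), np.nan)
    wf = np.empty((freqs.n_pops, freqs.n_snps))
    for l in range(freqs.n_snps):
        v = p[:, l]
        if np.isnan(v).any():                      # impute by population mean
            v = np.where(np.isnan(v), mean_p, v)
        wf[:, l] = _whiten(chol_inv, v)
        if wf[:, l].std() == 0:
            continue
        for j in range(len(variables)):
            rho[l, j] = stats.spearmanr(wf[:, l], wx[:, j]).statistic
    stat = np.nanmax(np.abs(rho), axis=1)
    order = np.argsort(-np.nan_to_num(stat, nan=-np.inf))
    n_top = max(1, int(np.floor(top_fraction * freqs.n_snps)))
    flag = np.zeros(freqs.n_snps, dtype=bool)
    flag[order[:n_top]] = True

    table = pd.DataFrame({"snp": freqs.snp_ids, "abs_rho_max": stat,
                          "outlier": flag})
    for j, v in enumerate(variables):
        table[f"rho_{v}"] = rho[:, j]

    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(freqs.n_snps)
        for _ in range(n_perm):
            idx = rng.permutation(freqs.n_pops)
            perm_stat = np.abs(np.array([
                [stats.spearmanr(wf[:, l], wx[idx, j]).statistic
                 for j in range(len(variables))]
                for l in range(freqs.n_snps)])).max(axis=1)
            exceed += perm_stat >= stat
        table["p_perm"] = (exceed + 1) / (n_perm + 1)

    return OutlierResult(table=table, params={"top_fraction": top_fraction,
                                              "n_perm": n_perm, "seed": seed,
                                              "variables": variables})
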