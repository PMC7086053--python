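"""Ordination summaries of genotypic structure: PCA and DAPC.

Missing genotypes are mean-imputed per SNP before ordination; columns are
centered and scaled to unit variance.  DAPC runs linear discriminant
analysis on retained principal-component scores with externally supplied
cluster labels (or k-means labels computed on the PC scores), and reports a
softmax posterior over clusters from discriminant-space distances to the
cluster centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .qc import MISSING, GenotypeMatrix

__all__ = ["OrdinationResult", "genotype_pca", "dapc", "kmeans_labels"]


@dataclass
class OrdinationResult:
    scores: np.ndarray                 # individuals x retained axes
    eigenvalues: np.ndarray
    var_explained: np.ndarray          # fractions of total variance
    loadings: np.ndarray | None = None  # SNPs x axes (PCA only)
    labels: np.ndarray | None = None   # DAPC cluster labels per individual
    posterior: np.ndarray | None = None  # DAPC assignment probabilities
    classes: np.ndarray | None = None


def _imputed_scaled(g: GenotypeMatrix):
    """Mean-impute missing entries per SNP, then center/scale columns.

    Returns the scaled matrix and the indices of retained (variable) SNPs.
    """
    x = g.genotypes.astype(float)
    miss = x == MISSING
    x[miss] = np.nan
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(miss)
    x[inds] = np.take(col_mean, inds[1])
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} zero-variance SNPs excluded from "
                      "ordination", stacklevel=3)
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    return x, np.flatnonzero(keep)


def _fix_signs(scores: np.ndarray, loadings: np.ndarray):
    """Deterministic axis orientation: largest-|loading| SNP positive."""
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return scores, loadings


def genotype_pca(g: GenotypeMatrix, n_axes: int | None = None) -> OrdinationResult:
    """PCA of the centered, unit-variance genotype matrix."""
    if g.n_individuals < 2:
        raise ValueError("PCA needs at least 2 individuals")
    x, _ = _imputed_scaled(g)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n = x.shape[0]
    eig = s ** 2 / (n - 1)
    total = eig.sum()
    k = min(n_axes or len(eig), len(eig))
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T.copy()
    scores, loadings = _fix_signs(scores, loadings)
    return OrdinationResult(scores=scores, eigenvalues=eig[:k],
                            var_explained=eig[:k] / total if total > 0 else eig[:k],
                            loadings=loadings)


def kmeans_labels(g: GenotypeMatrix, k: int, n_pcs: int | None = None,
                  seed: int = 0) -> np.ndarray:
    """k-means cluster labels on PC scores (fixed seed), for DAPC input."""
    from sklearn.cluster import KMeans

    pca = genotype_pca(g, n_axes=n_pcs)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(pca.scores).astype(str)


def _default_n_pcs(var_explained: np.ndarray, target: float = 0.90) -> int:
    cum = np.cumsum(var_explained)
    return int(np.searchsorted(cum, target) + 1)


def dapc(g: GenotypeMatrix, labels, n_pcs: int | None = None,
         n_da: int | None = None) -> OrdinationResult:
    """Discriminant analysis of principal components.

    ``labels`` gives one cluster label per individual.  ``n_pcs`` defaults to
    the number of axes explaining 90% of genotypic variance; ``n_da`` to
    (number of clusters - 1).  Posterior assignment is the softmax of
    -0.5 * squared discriminant-space distance to each cluster centroid.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    labels = np.asarray(labels)
    if labels.shape[0] != g.n_individuals:
        raise ValueError("one label per individual required")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("DAPC needs at least 2 clusters")
    if counts.min() < 2:
        bad = classes[counts < 2][0]
        raise ValueError(f"cluster {bad!r} has a single member")

    pca = genotype_pca(g)
    if n_pcs is None:
        n_pcs = _default_n_pcs(pca.var_explained)
    n_pcs = min(n_pcs, g.n_individuals - 1, pca.scores.shape[1])
    x = pca.scores[:, :n_pcs]

    n_da = min(n_da or classes.size - 1, classes.size - 1)
    lda = LinearDiscriminantAnalysis(solver="eigen", n_components=n_da)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear PCs are harmless here
        da_scores = lda.fit_transform(x, labels)

    centroids = np.vstack([da_scores[labels == c].mean(axis=0) for c in classes])
    d2 = ((da_scores[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    logp = -0.5 * d2
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=1, keepdims=True)

    # discriminant eigenvalues: between/within variance ratio per axis
    grand = da_scores.mean(axis=0)
    between = np.zeros(da_scores.shape[1])
    within = np.zeros(da_scores.shape[1])
    for c, cen in zip(classes, centroids):
        sub = da_scores[labels == c]
        between += len(sub) * (cen - grand) ** 2
        within += ((sub - cen) ** 2).sum(axis=0)
    eig = between / np.maximum(within, 1e-300)
    return OrdinationResult(scores=da_scores, eigenvalues=eig,
                            var_explained=eig / eig.sum() if eig.sum() > 0 else eig,
                            labels=labels, posterior=post, classes=classes)
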