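"""Redundancy analysis and environment/geography variance partitioning.

RDA regresses the (column-centered) population allele-frequency matrix on a
predictor set and measures the constrained variance fraction R^2, adjusted
by Ezekiel's formula ``1 - (1 - R^2)(n - 1)/(n - p - 1)``.  Geography
enters as Moran's eigenvector maps (MEM): eigenfunctions of a truncated,
doubly centered spatial weighting matrix (PCNM-style, truncation at the
longest minimum-spanning-tree edge).  Individual fractions (env-only,
geo-only, confounded) are assembled from adjusted R^2 of the single and
combined models so the ledger identity holds exactly; significance is by
permutation pseudo-F (rows for simple RDA, reduced-model residuals for
partial RDA); confounded fractions are not testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "MemBasis",
    "RdaResult",
    "PartitionTable",
    "mem_basis",
    "vif_screen",
    "forward_select",
    "rda",
    "variance_partition",
]


@dataclass
class MemBasis:
    coords: pd.DataFrame
    truncation: float
    eigenvectors: np.ndarray         # sites x functions, orthonormal
    eigenvalues: np.ndarray          # descending
    morans_i: np.ndarray
    morans_p: np.ndarray

    def frame(self, n: int | None = None) -> pd.DataFrame:
        n = n or self.eigenvectors.shape[1]
        return pd.DataFrame(self.eigenvectors[:, :n],
                            columns=[f"MEM{i + 1}" for i in range(n)])

    def significant(self, alpha: float = 0.05) -> list[int]:
        """Indices of functions with significant positive spatial correlation."""
        n = self.coords.shape[0]
        e_i = -1.0 / (n - 1)
        return [i for i in range(self.eigenvalues.size)
                if self.morans_p[i] <= alpha and self.morans_i[i] > e_i]


@dataclass(frozen=True)
class RdaResult:
    r2: float
    adj_r2: float
    eigenvalues: np.ndarray
    pseudo_f: float
    p_value: float | None
    n_perm: int
    seed: int | None
    n_predictors: int
    n_condition: int


@dataclass
class PartitionTable:
    """Adjusted-R^2 fraction ledger for environment vs geography."""

    env_total: float
    geo_total: float
    env_given_geo: float
    geo_given_env: float
    confounded: float
    total_explained: float
    p_values: dict[str, float]

    @property
    def total_unexplained(self) -> float:
        return 1.0 - self.total_explained

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("F ~ env.", self.env_total, self.p_values.get("env_total")),
            ("F ~ geo.", self.geo_total, self.p_values.get("geo_total")),
            ("F ~ env. | geo.", self.env_given_geo, self.p_values.get("env_given_geo")),
            ("F ~ geo. | env.", self.geo_given_env, self.p_values.get("geo_given_env")),
            ("Confounded (env. + geo.)", self.confounded, None),
            ("Total explained", self.total_explained, None),
            ("Total unexplained", self.total_unexplained, None),
        ]
        return pd.DataFrame(rows, columns=["fraction", "adj_r2", "p_value"])


def _morans_i(v: np.ndarray, w: np.ndarray) -> float:
    n = v.size
    vc = v - v.mean()
    s0 = w.sum()
    return float(n / s0 * (vc @ w @ vc) / (vc @ vc))


def mem_basis(coords: pd.DataFrame, truncation: str | float = "mst-max",
              n_perm: int = 999, seed: int = 0) -> MemBasis:
    """Moran's eigenvector maps from site coordinates.

    Distances are Euclidean on (lon, lat); the connectivity threshold t is
    the longest minimum-spanning-tree edge (or a numeric override); weights
    are ``1 - (d/(4t))^2`` within t, 0 beyond; the weight matrix is doubly
    centered and eigendecomposed; positive-eigenvalue functions are
    returned with per-function Moran's I and a one-sided permutation p.
    """
    xy = coords[["lon", "lat"]].to_numpy(float)
    n = xy.shape[0]
    if n < 4:
        raise ValueError("MEM needs at least 4 sites")
    d = squareform(pdist(xy))
    off = d[np.triu_indices(n, 1)]
    if np.any(off == 0):
        raise ValueError("coincident sites: jitter coordinates before MEM")
    if truncation == "mst-max":
        mst = minimum_spanning_tree(d)
        t = float(mst.data.max())
    else:
        t = float(truncation)
    w = np.where((d <= t) & (d > 0), 1.0 - (d / (4.0 * t)) ** 2, 0.0)
    np.fill_diagonal(w, 0.0)

    ones = np.ones((n, n)) / n
    c = np.eye(n) - ones
    b = c @ w @ c
    b = (b + b.T) / 2
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(abs(evals[0]), 1.0)
    evals, evecs = evals[pos], evecs[:, pos]
    # deterministic sign: largest-|entry| site positive
    for k in range(evecs.shape[1]):
        j = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[j, k] < 0:
            evecs[:, k] *= -1

    rng = np.random.default_rng(seed)
    mi = np.array([_morans_i(evecs[:, k], w) for k in range(evecs.shape[1])])
    pvals = np.empty_like(mi)
    for k in range(mi.size):
        count = 0
        for _ in range(n_perm):
            if _morans_i(rng.permutation(evecs[:, k]), w) >= mi[k]:
                count += 1
        pvals[k] = (count + 1) / (n_perm + 1)
    return MemBasis(coords=coords, truncation=t, eigenvectors=evecs,
                    eigenvalues=evals, morans_i=mi, morans_p=pvals)


def vif_screen(x: pd.DataFrame, vif_max: float = 10.0):
    """Iteratively drop the highest-VIF column until all VIF <= ``vif_max``.

    VIF_j = 1/(1 - R^2_j) from regressing column j on the others (with
    intercept).  Perfect collinearity gives infinite VIF; among ties the
    later-listed column is dropped first.  Returns (kept column names,
    VIF table of the final set).
    """
    if x.shape[1] < 2:
        raise ValueError("VIF screen needs at least 2 columns")
    cols = list(x.columns)

    def vifs(names):
        arr = x[names].to_numpy(float)
        out = []
        for j in range(len(names)):
            y = arr[:, j]
            others = np.delete(arr, j, axis=1)
            a = np.column_stack([np.ones(len(y)), others])
            coef, *_ = np.linalg.lstsq(a, y, rcond=None)
            resid = y - a @ coef
            ss_tot = ((y - y.mean()) ** 2).sum()
            r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
            out.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
        return np.array(out)

    while len(cols) >= 2:
        v = vifs(cols)
        if np.nanmax(v) <= vif_max:
            break
        worst = np.max(v)
        # later-listed dropped first on ties
        j = max(i for i in range(len(cols)) if v[i] == worst)
        cols.pop(j)
    table = pd.DataFrame({"variable": cols,
                          "vif": vifs(cols) if len(cols) >= 2 else [1.0] * len(cols)})
    return cols, table


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0)


def _fit_fraction(y: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    """SS(fitted) of least squares of y on centered x, plus fitted values.

    Rank-aware: near-zero singular directions (e.g. predictors fully
    residualized away by a conditioning set) are excluded from the
    projection rather than amplified.
    """
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    u = u[:, s > max(tol, 1e-12)]
    fitted = u @ (u.T @ y)
    return float((fitted ** 2).sum()), fitted


def rda(response, predictors, condition=None, n_perm: int = 999,
        seed: int | None = 0) -> RdaResult:
    """(Partial) redundancy analysis with a permutation pseudo-F test.

    ``response`` rows are populations (columns centered here); in the
    partial case both response and predictors are residualized on the
    conditioning set, and fractions are reported relative to the total
    response variance.  The permutation scheme follows standard practice:
    rows of the response for simple RDA, reduced-model residuals for
    partial RDA.
    """
    y = _center(np.asarray(response, float))
    x = _center(np.asarray(predictors, float))
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if y.shape[0] != n:
        raise ValueError("response and predictors disagree on rows")
    ss_total = float((y ** 2).sum())
    if ss_total == 0:
        raise ValueError("constant response")

    q = 0
    r2_cond = 0.0
    if condition is not None:
        z = _center(np.asarray(condition, float))
        if z.ndim == 1:
            z = z[:, None]
        q = z.shape[1]
        ss_cond, fit_c = _fit_fraction(y, z)
        r2_cond = ss_cond / ss_total
        y = y - fit_c
        qz, _ = np.linalg.qr(z)
        x = x - qz @ (qz.T @ x)
    if n <= p + q + 1:
        raise ValueError("insufficient degrees of freedom")

    ss_fit, fitted = _fit_fraction(y, x)
    r2 = ss_fit / ss_total
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if p > 0 else r2
    resid_frac = max(1.0 - r2 - r2_cond, 1e-300)
    f_obs = (r2 / p) / (resid_frac / (n - p - q - 1))
    # canonical eigenvalues: PCA of the fitted values
    sing = np.linalg.svd(fitted, compute_uv=False)
    eig = sing ** 2

    p_value = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            yp = y[rng.permutation(n)]       # reduced-model residuals in partial case
            ss_p, _ = _fit_fraction(yp, x)
            r2p = ss_p / ss_total
            resid_p = max(1.0 - r2p - r2_cond, 1e-300)
            fp = (r2p / p) / (resid_p / (n - p - q - 1))
            if fp >= f_obs:
                count += 1
        p_value = (count + 1) / (n_perm + 1)
    return RdaResult(r2=r2, adj_r2=adj, eigenvalues=eig, pseudo_f=f_obs,
                     p_value=p_value, n_perm=n_perm or 0, seed=seed,
                     n_predictors=p, n_condition=q)


def forward_select(response, candidates: pd.DataFrame, alpha: float = 0.05,
                   n_perm: int = 999, seed: int = 0) -> list[str]:
    """Permutation forward selection of predictors for RDA.

    At each step the candidate adding the most adjusted R^2 is tested
    (marginal permutation p, conditioning on the already-selected set) and
    added if p <= ``alpha``.  Selection also stops once the cumulative
    adjusted R^2 exceeds the global (all-candidate) model's adjusted R^2 —
    the standard double stopping rule.
    """
    names = list(candidates.columns)
    y = np.asarray(response, float)
    global_adj = rda(y, candidates.to_numpy(float), n_perm=0).adj_r2
    selected: list[str] = []
    rng = np.random.default_rng(seed)
    while True:
        remaining = [c for c in names if c not in selected]
        if not remaining:
            break
        best, best_adj = None, -np.inf
        for c in remaining:
            cols = selected + [c]
            adj = rda(y, candidates[cols].to_numpy(float), n_perm=0).adj_r2
            if adj > best_adj + 1e-12:
                best_adj, best = adj, c
        cond = candidates[selected].to_numpy(float) if selected else None
        res = rda(y, candidates[[best]].to_numpy(float), condition=cond,
                  n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        if res.p_value is None or res.p_value > alpha:
            break
        selected.append(best)
        if best_adj >= global_adj - 1e-12:
            break
    return selected


def variance_partition(response, env: pd.DataFrame, geo: pd.DataFrame,
                       n_perm: int = 999, seed: int = 0) -> PartitionTable:
    """Partition response variance into env-only, geo-only and confounded.

    Fractions are adjusted R^2 assembled by subtraction from the env-only,
    geo-only and combined models, so individual + confounded = total
    explained exactly.  The four testable fractions get permutation
    p-values; the confounded fraction has none.
    """
    overlap = set(env.columns) & set(geo.columns)
    if overlap:
        raise ValueError(f"variable names shared across sets: {sorted(overlap)}")
    y = np.asarray(response, float)
    e = env.to_numpy(float)
    g = geo.to_numpy(float)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2 ** 31, size=4)

    r_env = rda(y, e, n_perm=n_perm, seed=int(seeds[0]))
    r_geo = rda(y, g, n_perm=n_perm, seed=int(seeds[1]))
    r_all = rda(y, np.column_stack([e, g]), n_perm=0)
    r_env_geo = rda(y, e, condition=g, n_perm=n_perm, seed=int(seeds[2]))
    r_geo_env = rda(y, g, condition=e, n_perm=n_perm, seed=int(seeds[3]))

    ab, bc, abc = r_env.adj_r2, r_geo.adj_r2, r_all.adj_r2
    a = abc - bc
    c = abc - ab
    b = ab + bc - abc
    return PartitionTable(
        env_total=ab, geo_total=bc, env_given_geo=a, geo_given_env=c,
        confounded=b, total_explained=abc,
        p_values={"env_total": r_env.p_value, "geo_total": r_geo.p_value,
                  "env_given_geo": r_env_geo.p_value,
                  "geo_given_env": r_geo_env.p_value})
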