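"""Geographic and environmental distance matrices and the Mantel test.

Dissecting isolation by distance (IBD) from isolation by environment (IBE)
needs three pairwise-distance matrices among populations — geographic,
environmental (Euclidean on scaled/centered variables), and genetic
(linearized FST) — and a permutation test of matrix correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

__all__ = [
    "MantelResult",
    "geographic_distances",
    "environmental_distances",
    "mantel_test",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    seed: int | None = None


def _haversine_km(lon, lat):
    lam, phi = np.radians(lon), np.radians(lat)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = (np.sin(dphi / 2) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def geographic_distances(coords: pd.DataFrame,
                         metric: str = "haversine") -> pd.DataFrame:
    """Pairwise site distances from decimal-degree coordinates.

    ``haversine`` (default) gives great-circle km; ``euclidean-degrees``
    gives planar Euclidean distance on the raw coordinates.
    """
    lon = coords["lon"].to_numpy(float)
    lat = coords["lat"].to_numpy(float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 360):
        raise ValueError("longitude outside [-360, 360]")
    if metric == "haversine":
        d = _haversine_km(lon, lat)
    elif metric == "euclidean-degrees":
        xy = np.column_stack([lon, lat])
        d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    labels = coords["population"].tolist() if "population" in coords else None
    return pd.DataFrame(d, index=labels, columns=labels)


def environmental_distances(env: pd.DataFrame,
                            variables: list[str] | None = None) -> pd.DataFrame:
    """Euclidean distance on variables standardized to mean 0, sd 1 (sample sd)."""
    variables = variables or [c for c in env.columns if c != "population"]
    if not variables:
        raise ValueError("at least one variable required")
    x = env[variables].to_numpy(float)
    if np.isnan(x).any():
        raise ValueError("missing values in environmental variables")
    sd = x.std(axis=0, ddof=1)
    for j, v in enumerate(variables):
        if sd[j] == 0:
            raise ValueError(f"variable {v!r} has zero variance")
    z = (x - x.mean(axis=0)) / sd
    d = np.sqrt(((z[:, None] - z[None, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    labels = env["population"].tolist() if "population" in env else None
    return pd.DataFrame(d, index=labels, columns=labels)


def _as_square(d) -> np.ndarray:
    a = d.to_numpy(float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.max(np.abs(a - a.T)) > 1e-12:
        raise ValueError("distance matrix must be symmetric")
    return a


def mantel_test(d1, d2, n_perm: int = 999, seed: int | None = None,
                exhaustive: bool = False) -> MantelResult:
    """One-sided (positive association) Mantel test.

    r is the Pearson correlation of upper-triangle entries; the null permutes
    the rows and columns of ``d2`` simultaneously.  With random permutations
    ``p = (#{r_perm >= r_obs} + 1) / (n_perm + 1)``; with ``exhaustive=True``
    all n! orderings (identity included) are enumerated and
    ``p = #{r_perm >= r_obs} / n!``.
    """
    a, b = _as_square(d1), _as_square(d2)
    if a.shape != b.shape:
        raise ValueError("matrices must share shape")
    n = a.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 entities")
    if (isinstance(d1, pd.DataFrame) and isinstance(d2, pd.DataFrame)
            and list(d1.index) != list(d2.index)):
        raise ValueError("matrix labels do not match")
    iu = np.triu_indices(n, 1)
    va = a[iu]
    if va.std() == 0 or b[iu].std() == 0:
        raise ValueError("constant distance matrix: correlation undefined")

    def corr(mat):
        vb = mat[iu]
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = corr(b)
    if exhaustive:
        count = total = 0
        for perm in permutations(range(n)):
            idx = np.array(perm)
            if corr(b[np.ix_(idx, idx)]) >= r_obs - 1e-12:
                count += 1
            total += 1
        return MantelResult(r=r_obs, p_value=count / total, n_perm=total, seed=None)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        if corr(b[np.ix_(idx, idx)]) >= r_obs:
            count += 1
    return MantelResult(r=r_obs, p_value=(count + 1) / (n_perm + 1),
                        n_perm=n_perm, seed=seed)
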