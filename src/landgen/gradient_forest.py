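"""Gradient-forest turnover modeling of allele-frequency composition.

A gradient forest fits one random-forest regression per SNP (population
allele frequency on environmental predictors) and aggregates, over all SNPs
with positive out-of-bag R^2, the split-impurity improvements along each
predictor axis into a monotone cumulative-importance "turnover" function
F_p.  Each SNP contributes split mass scaled to its R^2-weighted per-
predictor importance; bin masses are normalized by the density of observed
predictor values before cumulation, and the curve is rescaled to end at the
predictor's overall importance I_p (the mean R^2-weighted importance over
positive-R^2 SNPs).  Transforming a climate grid through the F_p maps each
location into "genomic composition" space, whose first three principal
components color the landscape (RGB).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forest import fit_random_forest
from .qc import AlleleFreqMatrix
from .synthetic import ClimateGrid

__all__ = [
    "GFConfig",
    "TurnoverModel",
    "GenomicComposition",
    "fit_gf",
    "select_predictors",
    "transform_grid",
    "pca_rgb",
]


@dataclass(frozen=True)
class GFConfig:
    n_trees: int = 2000
    min_poly_pops: int = 5
    n_bins: int = 201
    seed: int = 0
    positive_r2_only: bool = True   # aggregation over SNPs with OOB R^2 > 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class TurnoverModel:
    """Fitted turnover functions and importance ledger."""

    predictors: list[str]
    bin_edges: dict[str, np.ndarray]       # per predictor, n_bins+1 edges
    cumulative: dict[str, np.ndarray]      # F_p at the edges; [0] = 0
    importance: dict[str, float]           # I_p = F_p(max observed)
    snp_r2: pd.Series                      # OOB R^2 per fitted SNP
    snp_importance: pd.DataFrame           # R^2-weighted importance per (SNP, predictor)
    config: GFConfig = field(default_factory=GFConfig)

    def ranked_predictors(self) -> list[str]:
        return sorted(self.predictors, key=lambda p: -self.importance[p])

    def turnover(self, predictor: str, x: np.ndarray) -> np.ndarray:
        """Evaluate F_p with flat extrapolation beyond the fitted range."""
        return np.interp(np.asarray(x, float), self.bin_edges[predictor],
                         self.cumulative[predictor])

    # --- JSON round-trip -------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "predictors": self.predictors,
            "bin_edges": {p: self.bin_edges[p].tolist() for p in self.predictors},
            "cumulative": {p: self.cumulative[p].tolist() for p in self.predictors},
            "importance": self.importance,
            "snp_r2": self.snp_r2.to_dict(),
            "config": {"n_trees": self.config.n_trees,
                       "min_poly_pops": self.config.min_poly_pops,
                       "n_bins": self.config.n_bins, "seed": self.config.seed,
                       "positive_r2_only": self.config.positive_r2_only},
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TurnoverModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        cfg = GFConfig(**payload["config"])
        return cls(
            predictors=payload["predictors"],
            bin_edges={p: np.array(v) for p, v in payload["bin_edges"].items()},
            cumulative={p: np.array(v) for p, v in payload["cumulative"].items()},
            importance=payload["importance"],
            snp_r2=pd.Series(payload["snp_r2"]),
            snp_importance=pd.DataFrame(), config=cfg)


@dataclass
class GenomicComposition:
    """Cells x predictors matrix of turnover-transformed climate values."""

    table: pd.DataFrame        # cell, lon, lat, then one column per predictor
    predictors: list[str]

    def values(self) -> np.ndarray:
        return self.table[self.predictors].to_numpy(float)


def _poly_filter(freqs: AlleleFreqMatrix, min_poly_pops: int) -> AlleleFreqMatrix:
    if min_poly_pops <= 0:
        return freqs
    poly = np.nansum((freqs.freq > 0) & (freqs.freq < 1), axis=0)
    return freqs.take_snps(np.flatnonzero(poly >= min_poly_pops))


def fit_gf(freqs: AlleleFreqMatrix, env: pd.DataFrame,
           config: GFConfig = GFConfig(),
           variables: list[str] | None = None) -> TurnoverModel:
    """Fit the gradient forest; see module docstring for the aggregation."""
    variables = variables or [c for c in env.columns if c != "population"]
    if len(variables) < 1:
        raise ValueError("at least one predictor required")
    if freqs.n_pops < 5:
        raise ValueError("gradient forest needs at least 5 populations")
    freqs = _poly_filter(freqs, config.min_poly_pops)
    if freqs.n_snps == 0:
        raise ValueError("no SNPs left after the polymorphism filter")

    x = env.set_index("population").loc[list(freqs.populations), variables] \
        .to_numpy(float)
    p_mat = freqs.freq
    col_mean = np.nanmean(p_mat, axis=0)

    n_pred = len(variables)
    rng = np.random.default_rng(config.seed)
    snp_seeds = rng.integers(0, 2 ** 31 - 1, freqs.n_snps)

    r2 = np.empty(freqs.n_snps)
    raw_imp = np.zeros((freqs.n_snps, n_pred))
    splits = []                      # per SNP: (feature, threshold, improvement)
    for l in range(freqs.n_snps):
        y = p_mat[:, l]
        if np.isnan(y).any():
            y = np.where(np.isnan(y), col_mean[l], y)
        fit = fit_random_forest(x, y, n_trees=config.n_trees,
                                seed=int(snp_seeds[l]))
        r2[l] = fit.oob_r2
        raw_imp[l] = np.clip(fit.importance, 0.0, None)
        splits.append((fit.split_feature, fit.split_threshold,
                       fit.split_improvement))

    use = r2 > 0 if config.positive_r2_only else np.ones(freqs.n_snps, bool)
    if not use.any():
        raise ValueError("no predictive SNPs (all out-of-bag R^2 <= 0)")

    # R^2-weighted importance share per SNP
    share = np.zeros_like(raw_imp)
    tot = raw_imp.sum(axis=1)
    nz = tot > 0
    share[nz] = raw_imp[nz] / tot[nz, None]
    weighted = share * np.clip(r2, 0.0, None)[:, None]   # I_{s,p}
    overall = weighted[use].mean(axis=0)                 # I_p

    bin_edges, cumulative, importance = {}, {}, {}
    for j, pred in enumerate(variables):
        lo, hi = x[:, j].min(), x[:, j].max()
        if hi <= lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, config.n_bins + 1)
        dens, _ = np.histogram(x[:, j], bins=edges)
        mass = np.zeros(config.n_bins)
        for l in np.flatnonzero(use):
            sf, st, si = splits[l]
            sel = sf == j
            if not sel.any() or weighted[l, j] <= 0:
                continue
            m, _ = np.histogram(st[sel], bins=edges, weights=si[sel])
            s = m.sum()
            if s > 0:
                mass += m / s * weighted[l, j]
        # density normalization: discount bins dense in observations
        mean_dens = max(dens.sum() / config.n_bins, 1e-12)
        norm_dens = np.where(dens > 0, dens, mean_dens)
        mass = mass / norm_dens
        cum = np.concatenate([[0.0], np.cumsum(mass)])
        if cum[-1] > 0:
            cum *= overall[j] / cum[-1]
        bin_edges[pred] = edges
        cumulative[pred] = cum
        importance[pred] = float(overall[j])
        assert np.all(np.diff(cum) >= -1e-12), "turnover must be non-decreasing"
        assert cum[0] == 0.0 and cum[-1] <= overall[j] + 1e-9

    snp_imp = pd.DataFrame(weighted, index=freqs.snp_ids, columns=variables)
    return TurnoverModel(predictors=list(variables), bin_edges=bin_edges,
                         cumulative=cumulative, importance=importance,
                         snp_r2=pd.Series(r2, index=freqs.snp_ids),
                         snp_importance=snp_imp, config=config)


def select_predictors(model: TurnoverModel, env: pd.DataFrame,
                      r_max: float = 0.8) -> list[str]:
    """Greedy Pearson-|r| pruning in descending-importance order.

    A predictor is kept iff its absolute Pearson correlation with every
    already-kept predictor is <= ``r_max``.
    """
    ranked = model.ranked_predictors()
    x = env[ranked].to_numpy(float)
    corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(corr)
    kept: list[int] = []
    for i in range(len(ranked)):
        if all(abs(corr[i, j]) <= r_max for j in kept):
            kept.append(i)
    return [ranked[i] for i in kept]


def transform_grid(model: TurnoverModel, grid: ClimateGrid) -> GenomicComposition:
    """Map every grid cell through the turnover functions.

    Values beyond the fitted range clamp to F_p = 0 / I_p (turnover is
    undefined where no splits were observed).
    """
    missing = [p for p in model.predictors if p not in grid.table.columns]
    if missing:
        raise KeyError(f"grid lacks predictor column(s): {missing}")
    out = grid.table[["cell", "lon", "lat"]].copy()
    for p in model.predictors:
        out[p] = model.turnover(p, grid.table[p].to_numpy(float))
    return GenomicComposition(table=out, predictors=list(model.predictors))


def pca_rgb(comp: GenomicComposition) -> pd.DataFrame:
    """First three PCs of the composition matrix mapped to RGB in [0, 255].

    Degenerate axes (rank deficit) get the mid-gray channel value 128.
    """
    x = comp.values()
    if x.shape[0] < 3:
        raise ValueError("RGB mapping needs at least 3 cells")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    out = comp.table[["cell", "lon", "lat"]].copy()
    channels = ["r", "g", "b"]
    if rank < 3:
        warnings.warn(f"composition rank {rank} < 3: remaining channels set "
                      "to 128", stacklevel=2)
    for k, ch in enumerate(channels):
        if k < rank:
            load = vt[k]
            sign = 1.0 if load[np.argmax(np.abs(load))] >= 0 else -1.0
            score = sign * u[:, k] * s[k]
            span = score.max() - score.min()
            vals = (score - score.min()) / span * 255.0 if span > 0 else np.full_like(score, 128.0)
            out[ch] = np.round(vals).astype(int)
        else:
            out[ch] = 128
    return out
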