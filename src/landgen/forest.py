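"""Compact random-forest regression core for per-SNP turnover modeling.

CART regression trees (variance-reduction splits, ``mtry`` features per
node, bootstrap resampling) with the three outputs turnover-function
construction needs and that must stay cheap at the scale of one forest per
SNP: out-of-bag predictions, out-of-bag permutation importances, and the
full list of (feature, threshold, impurity improvement) split records.
The kernel is numba-compiled; responses here have very few rows (one value
per population), so trees are tiny and thousands of 2000-tree forests fit
in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["ForestFit", "fit_random_forest"]


@dataclass
class ForestFit:
    """One fitted forest: OOB skill, importances, and split records."""

    oob_r2: float
    oob_prediction: np.ndarray           # NaN where never out-of-bag
    importance: np.ndarray               # per-feature OOB permutation MSE increase
    split_feature: np.ndarray
    split_threshold: np.ndarray
    split_improvement: np.ndarray        # SSE decrease on the bootstrap sample


@njit(cache=True)
def _best_split(xcol, yreg, n_reg):
    """Best threshold on one feature for a node region (sorted scan).

    Returns (gain, threshold, is_valid).  Gain is the SSE reduction
    S_L^2/n_L + S_R^2/n_R - S^2/n over the region.
    """
    order = np.argsort(xcol)
    xs = xcol[order]
    ys = yreg[order]
    total = 0.0
    for i in range(n_reg):
        total += ys[i]
    base = total * total / n_reg
    best_gain = 0.0
    best_thr = 0.0
    found = False
    left = 0.0
    for i in range(n_reg - 1):
        left += ys[i]
        if xs[i + 1] <= xs[i]:
            continue
        n_l = i + 1
        n_r = n_reg - n_l
        right = total - left
        gain = left * left / n_l + right * right / n_r - base
        if gain > best_gain + 1e-300:
            best_gain = gain
            best_thr = 0.5 * (xs[i] + xs[i + 1])
            found = True
    return best_gain, best_thr, found


@njit(cache=True)
def _predict_one(feat, thr, left, right, value, x):
    node = 0
    while feat[node] >= 0:
        if x[feat[node]] <= thr[node]:
            node = left[node]
        else:
            node = right[node]
    return value[node]


@njit(cache=True)
def _forest_kernel(X, y, n_trees, mtry, min_split, seed):
    np.random.seed(seed)
    n, p = X.shape
    max_nodes = 2 * n + 1
    max_splits = n_trees * n

    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n)
    imp = np.zeros(p)
    imp_trees = 0

    sp_feat = np.empty(max_splits, dtype=np.int64)
    sp_thr = np.empty(max_splits)
    sp_imp = np.empty(max_splits)
    n_sp = 0

    feat = np.empty(max_nodes, dtype=np.int64)
    thr = np.empty(max_nodes)
    left = np.empty(max_nodes, dtype=np.int64)
    right = np.empty(max_nodes, dtype=np.int64)
    value = np.empty(max_nodes)
    stack_node = np.empty(max_nodes, dtype=np.int64)
    stack_lo = np.empty(max_nodes, dtype=np.int64)
    stack_hi = np.empty(max_nodes, dtype=np.int64)
    features = np.arange(p)
    perm_buf = np.empty(n)

    for _t in range(n_trees):
        boot = np.random.randint(0, n, n)
        inbag = np.zeros(n, dtype=np.int64)
        for i in range(n):
            inbag[boot[i]] += 1
        idx = boot.copy()

        n_nodes = 1
        feat[0] = -1
        top = 0
        stack_node[0] = 0
        stack_lo[0] = 0
        stack_hi[0] = n
        top = 1
        while top > 0:
            top -= 1
            node = stack_node[top]
            lo = stack_lo[top]
            hi = stack_hi[top]
            n_reg = hi - lo
            s = 0.0
            for i in range(lo, hi):
                s += y[idx[i]]
            value[node] = s / n_reg
            feat[node] = -1
            if n_reg < min_split:
                continue
            # sample mtry distinct features (partial Fisher-Yates)
            for j in range(mtry):
                k = j + np.random.randint(0, p - j)
                tmp = features[j]
                features[j] = features[k]
                features[k] = tmp
            best_gain = 0.0
            best_thr = 0.0
            best_f = -1
            for j in range(mtry):
                f = features[j]
                xcol = np.empty(n_reg)
                yreg = np.empty(n_reg)
                for i in range(n_reg):
                    xcol[i] = X[idx[lo + i], f]
                    yreg[i] = y[idx[lo + i]]
                gain, t, ok = _best_split(xcol, yreg, n_reg)
                if ok and gain > best_gain:
                    best_gain = gain
                    best_thr = t
                    best_f = f
            if best_f < 0:
                continue
            # partition region in place
            i = lo
            j = hi - 1
            while i <= j:
                if X[idx[i], best_f] <= best_thr:
                    i += 1
                else:
                    tmp = idx[i]
                    idx[i] = idx[j]
                    idx[j] = tmp
                    j -= 1
            if i == lo or i == hi:
                continue
            feat[node] = best_f
            thr[node] = best_thr
            left[node] = n_nodes
            right[node] = n_nodes + 1
            sp_feat[n_sp] = best_f
            sp_thr[n_sp] = best_thr
            sp_imp[n_sp] = best_gain
            n_sp += 1
            stack_node[top] = n_nodes
            stack_lo[top] = lo
            stack_hi[top] = i
            top += 1
            stack_node[top] = n_nodes + 1
            stack_lo[top] = i
            stack_hi[top] = hi
            top += 1
            n_nodes += 2

        # out-of-bag predictions and per-tree permutation importance
        n_oob = 0
        for i in range(n):
            if inbag[i] == 0:
                n_oob += 1
        if n_oob == 0:
            continue
        oob_idx = np.empty(n_oob, dtype=np.int64)
        kpos = 0
        for i in range(n):
            if inbag[i] == 0:
                oob_idx[kpos] = i
                kpos += 1
        mse_base = 0.0
        for k in range(n_oob):
            i = oob_idx[k]
            pred = _predict_one(feat, thr, left, right, value, X[i])
            oob_sum[i] += pred
            oob_cnt[i] += 1.0
            d = y[i] - pred
            mse_base += d * d
        mse_base /= n_oob
        if n_oob >= 2:
            imp_trees += 1
            xrow = np.empty(p)
            for f in range(p):
                # permute this feature's OOB values
                for k in range(n_oob):
                    perm_buf[k] = X[oob_idx[k], f]
                for k in range(n_oob - 1, 0, -1):
                    r = np.random.randint(0, k + 1)
                    tmp2 = perm_buf[k]
                    perm_buf[k] = perm_buf[r]
                    perm_buf[r] = tmp2
                mse_perm = 0.0
                for k in range(n_oob):
                    i = oob_idx[k]
                    for f2 in range(p):
                        xrow[f2] = X[i, f2]
                    xrow[f] = perm_buf[k]
                    pred = _predict_one(feat, thr, left, right, value, xrow)
                    d = y[i] - pred
                    mse_perm += d * d
                mse_perm /= n_oob
                imp[f] += mse_perm - mse_base
    if imp_trees > 0:
        imp /= imp_trees
    return oob_sum, oob_cnt, imp, sp_feat[:n_sp], sp_thr[:n_sp], sp_imp[:n_sp]


def fit_random_forest(X: np.ndarray, y: np.ndarray, n_trees: int = 2000,
                      mtry: int | None = None, min_split: int = 5,
                      seed: int = 0) -> ForestFit:
    """Fit one regression forest; see module docstring for what is recorded.

    ``mtry`` defaults to max(p//3, 1) (regression convention); nodes with
    fewer than ``min_split`` bootstrap rows become leaves.  OOB R^2 is
    ``1 - MSE_oob / Var(y)``; it can be negative for unpredictable responses.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y disagree on sample count")
    if n_trees < 1:
        raise ValueError("need at least one tree")
    mtry = mtry or max(p // 3, 1)
    mtry = min(mtry, p)
    oob_sum, oob_cnt, imp, sf, st, si = _forest_kernel(
        X, y, n_trees, mtry, min_split, seed % (2 ** 31))
    with np.errstate(invalid="ignore"):
        oob_pred = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1), np.nan)
    seen = oob_cnt > 0
    var_y = y.var()
    if var_y > 0 and seen.any():
        mse = float(np.mean((y[seen] - oob_pred[seen]) ** 2))
        r2 = 1.0 - mse / var_y
    else:
        r2 = -np.inf if var_y == 0 else np.nan
    return ForestFit(oob_r2=float(r2), oob_prediction=oob_pred,
                     importance=imp, split_feature=sf,
                     split_threshold=st, split_improvement=si)
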