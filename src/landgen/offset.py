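"""Genetic offset between current and future climates.

The offset at a grid cell is the Euclidean distance between the cell's
current and future climates after both are mapped through the fitted
turnover functions — a climate-only proxy for how far the locally adapted
genomic composition would sit from the composition the future climate
favors.  It is computed in the full transformed-predictor space (no PCA
reduction) and is symmetric in the two epochs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gradient_forest import TurnoverModel, transform_grid
from .synthetic import ClimateGrid

__all__ = ["compute_offset", "summarize_offset"]


def compute_offset(model: TurnoverModel, current: ClimateGrid,
                   future: ClimateGrid) -> pd.DataFrame:
    """Per-cell offset table (cell, lon, lat, offset, scenario), sorted by cell."""
    cur_cells = set(current.table["cell"])
    fut_cells = set(future.table["cell"])
    if cur_cells != fut_cells:
        diff = sorted(cur_cells ^ fut_cells)
        raise ValueError(f"grids differ in cells (symmetric difference: {diff})")
    cur = transform_grid(model, current)
    fut = transform_grid(model, future)
    a = cur.table.sort_values("cell").reset_index(drop=True)
    b = fut.table.sort_values("cell").reset_index(drop=True)
    d = np.sqrt(((a[model.predictors].to_numpy(float)
                  - b[model.predictors].to_numpy(float)) ** 2).sum(axis=1))
    out = a[["cell", "lon", "lat"]].copy()
    out["offset"] = d
    out["scenario"] = future.epoch
    return out


def summarize_offset(grids, quantiles=(0.05, 0.25, 0.5, 0.75, 0.95),
                     thresholds=()) -> pd.DataFrame:
    """Summary (quantiles, mean, max, counts above thresholds) per scenario.

    ``grids`` is one offset table or a sequence of them; rows are scenarios.
    """
    if isinstance(grids, pd.DataFrame):
        grids = [grids]
    quantiles = list(quantiles)
    if not quantiles:
        raise ValueError("quantile list must be non-empty")
    rows = []
    for g in grids:
        if g.empty:
            raise ValueError("empty offset grid")
        vals = g["offset"].to_numpy(float)
        row = {"scenario": g["scenario"].iloc[0] if "scenario" in g else "",
               "n_cells": vals.size, "mean": vals.mean(), "max": vals.max()}
        for q in quantiles:
            row[f"q{q:g}"] = float(np.quantile(vals, q))
        for t in thresholds:
            row[f"n_above_{t:g}"] = int((vals > t).sum())
        rows.append(row)
    return pd.DataFrame(rows)
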