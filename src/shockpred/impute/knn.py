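"""Deterministic k-nearest-neighbour imputation.

Row distances are NaN-aware Euclidean on z-scored continuous coordinates:
d(x, y) = sqrt(n_total / n_shared * sum over mutually observed coords of
(x_i - y_i)^2); rows sharing no observed coordinate are at infinite
distance.  Continuous cells take the mean of the k nearest donors observed
in that variable, categorical cells the mode (ties by level order).
"""

from __future__ import annotations

import numpy as np

from ..errors import ImputationError
from ..matrix import CATEGORICAL, CONTINUOUS, FeatureMatrix
from .config import ImputationConfig, ImputationSet


def _nan_euclidean(Z: np.ndarray) -> np.ndarray:
    """Pairwise NaN-aware Euclidean distances (rows of Z; NaN = missing)."""
    n, d = Z.shape
    obs = ~np.isnan(Z)
    Zf = np.nan_to_num(Z, nan=0.0)
    sq = Zf**2
    # sum over shared coords of (x - y)^2, restricted to mutually observed dims
    shared = obs.astype(float) @ obs.T.astype(float)
    cross = Zf @ Zf.T
    x2 = sq @ obs.T.astype(float)     # sum x_i^2 over dims observed in both
    y2 = obs.astype(float) @ sq.T
    d2 = x2 + y2 - 2.0 * cross
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(shared > 0, d2 * (d / shared), np.inf)
    d2 = np.clip(d2, 0.0, None)
    return np.sqrt(d2)


def knn_impute(matrix: FeatureMatrix, config: ImputationConfig) -> ImputationSet:
    mask = matrix.mask
    cont = matrix.continuous_names()
    if not cont:
        raise ImputationError("KNN imputation needs at least one continuous variable")
    Z = np.column_stack([
        matrix.df[name].to_numpy(dtype=float) for name in cont
    ])
    obs_mean = np.nanmean(Z, axis=0)
    obs_sd = np.nanstd(Z, axis=0)
    obs_sd[obs_sd == 0] = 1.0
    Zs = (Z - obs_mean) / obs_sd

    dist = _nan_euclidean(Zs)
    np.fill_diagonal(dist, np.inf)

    df = matrix.df.copy()
    n = len(df)
    for name in matrix.variables:
        miss_idx = np.flatnonzero(mask[name].to_numpy())
        if miss_idx.size == 0:
            continue
        donors_mask = ~mask[name].to_numpy()
        if not donors_mask.any():
            raise ImputationError(f"column {name!r} has no observed values")
        meta = matrix.meta_for(name)
        donor_pos = np.flatnonzero(donors_mask)
        vals = df[name].to_numpy(dtype=float if meta.vtype == CONTINUOUS else object)
        for i in miss_idx:
            d = dist[i, donor_pos]
            finite = np.isfinite(d)
            if not finite.any():
                raise ImputationError(
                    f"row {df.index[i]} shares no observed coordinate with any donor"
                )
            cand = donor_pos[finite]
            order = np.argsort(d[finite], kind="stable")
            k = min(config.knn_k, cand.size)
            chosen = cand[order[:k]]
            if meta.vtype == CONTINUOUS:
                df.iloc[i, df.columns.get_loc(name)] = float(
                    np.mean(vals[chosen].astype(float))
                )
            else:
                levels = list(meta.levels or ())
                counts = {lev: 0 for lev in levels}
                for v in vals[chosen]:
                    counts[v] += 1
                best = max(levels, key=lambda lev: (counts[lev], -levels.index(lev)))
                df.iloc[i, df.columns.get_loc(name)] = best
    out = FeatureMatrix(df, matrix.meta)
    return ImputationSet([out], "knn", config, [{"note": "deterministic"}])
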