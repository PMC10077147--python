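"""Chained-equation imputation with predictive mean matching.

One stochastic chain per completed dataset: columns are visited in order of
ascending missingness, each incomplete column is regressed on all other
(currently completed) columns, continuous cells are filled by PMM over the
k donors with the closest predictions, categorical cells by a draw from the
predicted class distribution.  Sweeps repeat until the mean absolute change
of imputed continuous cells (z-scored) drops below ``tol`` or ``max_iter``
is reached.

The conditional learner is deliberately pluggable and defaults to a
histogram gradient-boosted tree ensemble from scikit-learn; the chained
loop, visit order, PMM and convergence logic live here.
"""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, HistGradientBoostingRegressor
from sklearn.linear_model import LogisticRegression, Ridge

from ..errors import ImputationError
from ..matrix import CATEGORICAL, CONTINUOUS, FeatureMatrix
from .config import ImputationConfig, ImputationSet

_GBT_DEFAULTS = {"max_iter": 60, "max_leaf_nodes": 31, "early_stopping": False}


def pmm_draw(
    pred_missing: float,
    pred_observed: np.ndarray,
    donor_values: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> float:
    """Sample one donor value among the k donors with the closest predictions.

    Ties at the k-th slot break by donor index order (stable sort), then one
    of the k candidates is drawn uniformly.
    """
    pred_observed = np.asarray(pred_observed, dtype=float)
    donor_values = np.asarray(donor_values)
    if donor_values.size == 0:
        raise ImputationError("PMM requires at least one donor")
    k = min(int(k), donor_values.size)
    dist = np.abs(pred_observed - float(pred_missing))
    order = np.argsort(dist, kind="stable")
    pick = order[int(rng.integers(k))]
    return donor_values[pick]


def _make_model(vtype: str, config: ImputationConfig, random_state: int):
    params = dict(config.model_params)
    if config.model == "gbt":
        params = {**_GBT_DEFAULTS, **params}
        cls = (HistGradientBoostingRegressor if vtype == CONTINUOUS
               else HistGradientBoostingClassifier)
        return cls(random_state=random_state, **params)
    if config.model == "linear":
        if vtype == CONTINUOUS:
            return Ridge(**params)
        return LogisticRegression(max_iter=500, **params)
    raise ImputationError(f"unknown MICE model {config.model!r}")


def _design_matrix(df: pd.DataFrame, matrix: FeatureMatrix, exclude: str) -> np.ndarray:
    """Numeric feature view of all columns except ``exclude`` (no NaN)."""
    blocks = []
    for m in matrix.meta:
        if m.name == exclude:
            continue
        if m.vtype == CONTINUOUS:
            col = df[m.name].to_numpy(dtype=float)
            sd = col.std() or 1.0
            blocks.append(((col - col.mean()) / sd)[:, None])
        else:
            vals = df[m.name].to_numpy(dtype=object)
            levels = m.levels or ()
            oh = np.zeros((len(df), len(levels)))
            for j, lev in enumerate(levels):
                oh[:, j] = (vals == lev).astype(float)
            blocks.append(oh)
    if not blocks:
        return np.zeros((len(df), 1))
    return np.hstack(blocks)


def _run_chain(
    matrix: FeatureMatrix,
    config: ImputationConfig,
    rng: np.random.Generator,
    visit_order: list[str],
    obs_sd: dict[str, float],
    log: list[dict[str, Any]],
    chain_id: int,
) -> FeatureMatrix:
    df = matrix.df.copy()
    mask = matrix.mask

    # initial fill: random draw from each column's observed values
    for name in visit_order:
        miss = mask[name].to_numpy()
        obs_vals = df.loc[~mask[name], name].to_numpy()
        fill_idx = rng.integers(obs_vals.size, size=int(miss.sum()))
        df.loc[miss, name] = obs_vals[fill_idx]

    prev_cont = {
        name: df.loc[mask[name], name].to_numpy(dtype=float)
        for name in visit_order
        if matrix.meta_for(name).vtype == CONTINUOUS
    }

    for sweep in range(config.max_iter):
        for name in visit_order:
            meta = matrix.meta_for(name)
            miss = mask[name].to_numpy()
            obs = ~miss
            X = _design_matrix(df, matrix, exclude=name)
            y_obs = df.loc[obs, name].to_numpy()
            model = _make_model(meta.vtype, config,
                                random_state=int(rng.integers(2**31 - 1)))
            if meta.vtype == CONTINUOUS:
                model.fit(X[obs], y_obs.astype(float))
                pred_obs = np.asarray(model.predict(X[obs]), dtype=float)
                pred_mis = np.asarray(model.predict(X[miss]), dtype=float)
                new = np.array([
                    pmm_draw(pm, pred_obs, y_obs.astype(float), config.pmm_k, rng)
                    for pm in pred_mis
                ])
                df.loc[miss, name] = new
            else:
                model.fit(X[obs], y_obs.astype(str))
                proba = np.asarray(model.predict_proba(X[miss]))
                classes = np.asarray(model.classes_, dtype=object)
                draws = [
                    classes[rng.choice(len(classes), p=proba[i] / proba[i].sum())]
                    for i in range(proba.shape[0])
                ]
                df.loc[miss, name] = pd.array(draws, dtype=object)

        # convergence: mean |change| of imputed continuous cells, z-scored
        changes = []
        for name, prev in prev_cont.items():
            cur = df.loc[mask[name], name].to_numpy(dtype=float)
            if cur.size:
                changes.append(np.abs(cur - prev) / obs_sd[name])
            prev_cont[name] = cur
        change = float(np.concatenate(changes).mean()) if changes else 0.0
        log.append({"chain": chain_id, "sweep": sweep + 1, "mean_abs_change": change})
        if change < config.tol:
            break

    return FeatureMatrix(df, matrix.meta)


def mice_impute(matrix: FeatureMatrix, config: ImputationConfig) -> ImputationSet:
    """Run ``config.m`` independent chains; returns one completed matrix each."""
    mask = matrix.mask
    incomplete = [n for n in matrix.variables if mask[n].any()]
    for name in incomplete:
        if mask[name].all():
            raise ImputationError(f"column {name!r} has no observed values")

    log: list[dict[str, Any]] = []
    if not incomplete:
        log.append({"note": "no missing cells; zero sweeps"})
        return ImputationSet([matrix.copy() for _ in range(config.m)],
                             "mice", config, log)

    # visit order: ascending missingness count, ties by column order
    counts = {n: int(mask[n].sum()) for n in incomplete}
    visit_order = sorted(incomplete, key=lambda n: (counts[n], matrix.variables.index(n)))

    obs_sd = {}
    for name in visit_order:
        if matrix.meta_for(name).vtype == CONTINUOUS:
            sd = float(matrix.df.loc[~mask[name], name].astype(float).std(ddof=0))
            obs_sd[name] = sd if sd > 0 else 1.0

    seeds = np.random.SeedSequence(config.seed).spawn(config.m)
    completed = [
        _run_chain(matrix, config, np.random.default_rng(s), visit_order,
                   obs_sd, log, chain_id=i)
        for i, s in enumerate(seeds)
    ]
    return ImputationSet(completed, "mice", config, log)
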