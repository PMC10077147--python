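"""Class rebalancing: SMOTE over-sampling followed by ENN cleaning.

SMOTE synthesizes minority rows by convex interpolation toward minority
nearest neighbours; Edited Nearest Neighbours then removes rows (original
or synthetic) whose k-NN majority vote contradicts their label.  Both steps
carry per-row provenance so cross-validation can assert the absence of
resampling leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError


@dataclass
class ResampleConfig:
    smote_k: int = 5
    target_ratio: float = 1.0   # minority:majority after over-sampling
    enn_k: int = 3
    vote_on_original: bool = False  # ENN votes from original rows only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smote_k < 1 or self.enn_k < 1:
            raise ConfigError("smote_k and enn_k must be >= 1")
        if not 0.0 < self.target_ratio <= 1.0:
            raise ConfigError("target_ratio must lie in (0, 1]")


@dataclass
class ResampledSet:
    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray        # "original" | "synthetic" per surviving row
    source_index: np.ndarray      # original-row index; -1 for synthetics
    parents: np.ndarray           # (n, 2) minority parent indices; -1 for originals
    removed: np.ndarray           # pre-ENN row positions removed by ENN
    counts: dict = field(default_factory=dict)


def _standardize(X: np.ndarray, continuous: np.ndarray) -> np.ndarray:
    Z = X.astype(float).copy()
    cols = Z[:, continuous]
    mean = cols.mean(axis=0)
    sd = cols.std(axis=0)
    sd[sd == 0] = 1.0
    Z[:, continuous] = (cols - mean) / sd
    return Z


def smote_oversample(
    X_minority: np.ndarray,
    n_new: int,
    k: int,
    rng: np.random.Generator,
    categorical_idx: Sequence[int] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``n_new`` synthetic minority rows.

    Each synthetic row is x + delta * (x_nn - x) with delta ~ U(0,1), x a
    uniformly sampled minority row and x_nn one of its k nearest minority
    neighbours (Euclidean on z-scored continuous features); categorical
    features are copied from the seed row x.  Returns ``(rows, parents)``
    where parents[i] = (seed index, neighbour index) into X_minority.
    """
    X_minority = np.asarray(X_minority, dtype=float)
    n, d = X_minority.shape
    if n < 2:
        raise ConfigError("SMOTE requires at least two minority rows")
    if n_new == 0:
        return np.empty((0, d)), np.empty((0, 2), dtype=int)
    k = min(int(k), n - 1)
    cat = np.zeros(d, dtype=bool)
    cat[list(categorical_idx)] = True
    Z = _standardize(X_minority, ~cat)[:, ~cat]
    sq = (Z**2).sum(axis=1)
    d2 = np.clip(sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T), 0.0, None)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]

    seeds = rng.integers(n, size=n_new)
    which = rng.integers(k, size=n_new)
    deltas = rng.random(n_new)
    neigh = nn[seeds, which]
    rows = X_minority[seeds].copy()
    cont = ~cat
    rows[:, cont] += deltas[:, None] * (X_minority[neigh][:, cont] - X_minority[seeds][:, cont])
    parents = np.column_stack([seeds, neigh])
    return rows, parents


def enn_clean(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    vote_pool: np.ndarray | None = None,
    standardize: bool = True,
) -> np.ndarray:
    """Surviving row indices after a single Edited-Nearest-Neighbours pass.

    A row is removed when the majority label among its k nearest neighbours
    (excluding itself, votes drawn from ``vote_pool`` — default: all rows)
    differs from its own.  Ties keep the row.  Single pass over the original
    set: removals do not cascade.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(X)
    if k >= n:
        raise ConfigError(f"enn_k = {k} must be < number of rows = {n}")
    pool = np.arange(n) if vote_pool is None else np.asarray(vote_pool)
    Z = _standardize(X, np.ones(X.shape[1], dtype=bool)) if standardize else X
    keep = []
    for i in range(n):
        cand = pool[pool != i]
        d2 = ((Z[cand] - Z[i]) ** 2).sum(axis=1)
        order = np.argsort(d2, kind="stable")[:k]
        votes = y[cand[order]]
        n_same = int((votes == y[i]).sum())
        if n_same * 2 >= len(votes):  # tie or majority agreement -> keep
            keep.append(i)
    return np.asarray(keep, dtype=int)


def smote_enn(
    X: np.ndarray,
    y: np.ndarray,
    config: ResampleConfig,
    categorical_idx: Sequence[int] = (),
    rng: np.random.Generator | None = None,
) -> ResampledSet:
    """SMOTE to ``target_ratio`` then one ENN pass over the combined set."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ConfigError("smote_enn expects binary labels")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    min_idx = np.flatnonzero(y == minority)
    n_target = int(round(config.target_ratio * n_maj))
    n_new = max(0, n_target - n_min)
    synth, parents_local = smote_oversample(
        X[min_idx], n_new, config.smote_k, rng, categorical_idx
    )
    parents = min_idx[parents_local] if len(parents_local) else np.empty((0, 2), dtype=int)

    X2 = np.vstack([X, synth])
    y2 = np.concatenate([y, np.full(len(synth), minority, dtype=y.dtype)])
    provenance = np.array(["original"] * len(X) + ["synthetic"] * len(synth))
    source_index = np.concatenate([np.arange(len(X)), np.full(len(synth), -1)])
    parent_rows = np.vstack([np.full((len(X), 2), -1, dtype=int), parents]) \
        if len(X2) else np.empty((0, 2), dtype=int)

    vote_pool = np.arange(len(X)) if config.vote_on_original else None
    keep = enn_clean(X2, y2, config.enn_k, vote_pool=vote_pool)
    removed = np.setdiff1d(np.arange(len(X2)), keep)

    kept_y = y2[keep]
    return ResampledSet(
        X=X2[keep], y=kept_y,
        provenance=provenance[keep],
        source_index=source_index[keep],
        parents=parent_rows[keep],
        removed=removed,
        counts={
            "minority_in": int(n_min), "majority_in": int(n_maj),
            "synthetic_created": int(len(synth)),
            "removed_by_enn": int(len(removed)),
            "minority_out": int((kept_y == minority).sum()),
            "majority_out": int((kept_y == majority).sum()),
        },
    )
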