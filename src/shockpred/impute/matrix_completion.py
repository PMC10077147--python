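"""SVD-based matrix completion: SoftImpute and IterativeSVD.

Both engines operate on the numeric mixed encoding and restore observed
cells exactly on output.  SoftImpute iterates Z <- SVT_lambda(P_obs(X) +
P_miss(Z)) where SVT soft-thresholds singular values at lambda; IterativeSVD
iterates a fixed-rank truncated-SVD reconstruction with observed entries
re-clamped each sweep.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from ..errors import ConfigError
from ..matrix import FeatureMatrix
from .config import ImputationConfig, ImputationSet
from .encode import encode_mixed


def svt(X: np.ndarray, lam: float) -> np.ndarray:
    """Singular value thresholding: shrink singular values by lam (floor 0)."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    s = np.maximum(s - lam, 0.0)
    return (U * s) @ Vt


def _svt_iterate(
    X: np.ndarray, miss: np.ndarray, Z: np.ndarray, lam: float,
    tol: float, max_iter: int, log: list[dict[str, Any]] | None = None,
) -> tuple[np.ndarray, bool]:
    """Fixed-lambda proximal iteration Z <- SVT(P_obs(X) + P_miss(Z))."""
    for it in range(max_iter):
        filled = np.where(miss, Z, X)
        Z_new = svt(filled, lam)
        denom = np.linalg.norm(Z) or 1.0
        delta = np.linalg.norm(Z_new - Z) / denom
        if log is not None:
            resid = np.where(miss, 0.0, X - Z_new)
            nuc = np.linalg.svd(Z_new, compute_uv=False).sum()
            log.append({
                "iter": it + 1, "rel_change": float(delta),
                "objective": float(0.5 * (resid**2).sum() + lam * nuc),
            })
        Z = Z_new
        if delta < tol:
            return Z, True
    return Z, False


def _soft_impute_core(
    X: np.ndarray, miss: np.ndarray, lam: float, tol: float, max_iter: int
) -> tuple[np.ndarray, list[dict[str, Any]]]:
    """Warm-started lambda continuation down to ``lam``, then iterate at lam.

    The ladder (halving from half the leading singular value of the
    zero-filled matrix) is the standard trick that keeps small-lambda runs
    out of the slow full-rank drift regime; the convergence log and the
    monotone-objective guarantee refer to the final fixed-lambda stage.
    """
    Z = np.where(miss, 0.0, X)
    log: list[dict[str, Any]] = []
    s_max = np.linalg.svd(Z, compute_uv=False)[0] if Z.size else 0.0
    lam_t = s_max / 2.0
    while lam_t > lam and lam_t > 1e-12:
        Z, _ = _svt_iterate(X, miss, Z, lam_t, max(tol, 1e-6), max_iter)
        lam_t /= 2.0
    Z, converged = _svt_iterate(X, miss, Z, lam, tol, max_iter, log=log)
    if not converged:
        log.append({"warning": f"soft_impute did not converge in {max_iter} iterations"})
    return np.where(miss, Z, X), log


def _holdout_lambda(
    X: np.ndarray, miss: np.ndarray, tol: float, max_iter: int, seed: int
) -> float:
    """Pick lambda on a 10% observed-entry holdout over a geometric grid."""
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(~miss)
    if len(obs_idx) < 20:
        return 0.0
    hold = obs_idx[rng.choice(len(obs_idx), size=max(1, len(obs_idx) // 10),
                              replace=False)]
    miss_cv = miss.copy()
    miss_cv[hold[:, 0], hold[:, 1]] = True
    s_max = np.linalg.svd(np.where(miss_cv, 0.0, X), compute_uv=False)[0]
    best_lam, best_err = 0.0, np.inf
    for frac in (0.5, 0.25, 0.1, 0.05, 0.01):
        lam = s_max * frac
        Z, _ = _soft_impute_core(X, miss_cv, lam, tol, max_iter)
        err = float(np.mean((Z[hold[:, 0], hold[:, 1]] - X[hold[:, 0], hold[:, 1]])**2))
        if err < best_err:
            best_lam, best_err = lam, err
    return best_lam


def soft_impute(matrix: FeatureMatrix, config: ImputationConfig) -> ImputationSet:
    X, decoder = encode_mixed(matrix, center=False)
    miss = np.isnan(X)
    log: list[dict[str, Any]] = []
    if not miss.any():
        log.append({"note": "no missing cells"})
        return ImputationSet([matrix.copy()], "soft_impute", config, log)
    lam = config.lam
    if lam is None:
        lam = _holdout_lambda(X, miss, config.tol, config.max_iter, config.seed)
        log.append({"lambda_selected": float(lam)})
    Z, core_log = _soft_impute_core(X, miss, lam, config.tol, config.max_iter)
    log.extend(core_log)
    return ImputationSet([decoder.decode(Z)], "soft_impute", config, log)


def iterative_svd_impute(matrix: FeatureMatrix, config: ImputationConfig) -> ImputationSet:
    X, decoder = encode_mixed(matrix, center=False)
    miss = np.isnan(X)
    if config.rank >= min(X.shape):
        raise ConfigError(
            f"rank {config.rank} must be < min(matrix dims) = {min(X.shape)}"
        )
    log: list[dict[str, Any]] = []
    if not miss.any():
        log.append({"note": "no missing cells; 0 iterations"})
        return ImputationSet([matrix.copy()], "iterative_svd", config, log)

    col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
    col_mean = np.nan_to_num(col_mean)
    Z = np.where(miss, col_mean[None, :], X)
    converged = False
    for it in range(config.max_iter):
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        Z_new = (U[:, :config.rank] * s[:config.rank]) @ Vt[:config.rank]
        Z_new = np.where(miss, Z_new, X)  # re-clamp observed entries
        denom = np.linalg.norm(Z) or 1.0
        delta = float(np.linalg.norm(Z_new - Z) / denom)
        log.append({"iter": it + 1, "rel_change": delta})
        Z = Z_new
        if delta < config.tol:
            converged = True
            break
    if not converged:
        log.append({"warning": f"iterative_svd did not converge in {config.max_iter} iterations"})
    return ImputationSet([decoder.decode(Z)], "iterative_svd", config, log)
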