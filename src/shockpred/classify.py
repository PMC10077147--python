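"""Bivariate screening, derived features, gradient-boosted classification,
and repeated stratified K-fold cross-validation with ROC/AUC aggregation.

The learner is delegated to scikit-learn's histogram gradient-boosted trees
behind a narrow train/score contract; fold construction, ROC computation,
leakage guarding, and aggregation are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError
from .matrix import CATEGORICAL, CONTINUOUS, FeatureMatrix
from .rebalance import ResampleConfig, smote_enn


@dataclass
class ClassifierConfig:
    n_estimators: int = 100
    num_leaves: int = 31
    class_weight: str = "balanced"  # "balanced" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ConfigError("n_estimators must be >= 1")
        if self.num_leaves < 2:
            raise ConfigError("num_leaves must be >= 2")
        if self.class_weight not in ("balanced", "none"):
            raise ConfigError("class_weight must be 'balanced' or 'none'")


@dataclass
class CVConfig:
    n_splits: int = 5
    n_repeats: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_splits < 2:
            raise ConfigError("n_splits must be >= 2")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")


@dataclass(frozen=True)
class BivariateResult:
    variable: str
    test: str          # "chi-squared" | "t" | "mann-whitney"
    statistic: float
    p: float


# --------------------------------------------------------------------------
# Screening & derived features
# --------------------------------------------------------------------------

def chi_squared_stat(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared on a contingency table (no continuity correction)."""
    stat, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(stat), float(p)


def _groups_normal(x0: np.ndarray, x1: np.ndarray, alpha: float = 0.05,
                   cap: int = 500) -> bool:
    for x in (x0, x1):
        sub = x[:cap]
        if len(sub) < 3 or np.ptp(sub) == 0:
            return False
        if stats.shapiro(sub).pvalue < alpha:
            return False
    return True


def bivariate_screen(
    matrix: FeatureMatrix, labels: np.ndarray
) -> tuple[list[BivariateResult], list[str]]:
    """Per-variable group comparison with type-appropriate tests.

    Categorical -> chi-squared on the contingency table; continuous ->
    unpaired t-test when both groups pass Shapiro–Wilk normality (alpha 0.05,
    n capped at 500), otherwise Mann–Whitney U.  Degenerate variables
    (single level / constant) are skipped and logged.
    """
    labels = np.asarray(labels)
    results: list[BivariateResult] = []
    skipped: list[str] = []
    for name in matrix.variables:
        col = matrix.df[name]
        meta = matrix.meta_for(name)
        if meta.vtype == CATEGORICAL:
            tab = pd.crosstab(col, labels)
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                skipped.append(name)
                continue
            stat, p = chi_squared_stat(tab.to_numpy())
            results.append(BivariateResult(name, "chi-squared", stat, p))
        else:
            vals = col.to_numpy(dtype=float)
            x0 = vals[labels == 0]
            x1 = vals[labels == 1]
            x0 = x0[~np.isnan(x0)]
            x1 = x1[~np.isnan(x1)]
            if x0.size < 2 or x1.size < 2 or (np.ptp(vals[~np.isnan(vals)]) == 0):
                skipped.append(name)
                continue
            if _groups_normal(x0, x1):
                res = stats.ttest_ind(x0, x1)
                results.append(BivariateResult(name, "t", float(res.statistic),
                                               float(res.pvalue)))
            else:
                res = stats.mannwhitneyu(x0, x1, alternative="two-sided")
                results.append(BivariateResult(name, "mann-whitney",
                                               float(res.statistic), float(res.pvalue)))
    return results, skipped


def shock_index(heart_rate, systolic_bp):
    """Heart rate / systolic blood pressure; non-positive BP -> NaN."""
    hr = np.asarray(heart_rate, dtype=float)
    sbp = np.asarray(systolic_bp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(sbp > 0, hr / sbp, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


# --------------------------------------------------------------------------
# Classifier & ROC
# --------------------------------------------------------------------------

def train_classifier(X: np.ndarray, y: np.ndarray, config: ClassifierConfig):
    """Fit the gradient-boosted scorer; returns the fitted estimator."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ConfigError("training labels contain a single class")
    clf = HistGradientBoostingClassifier(
        max_iter=config.n_estimators,
        max_leaf_nodes=config.num_leaves,
        class_weight="balanced" if config.class_weight == "balanced" else None,
        early_stopping=False,
        random_state=config.seed,
    )
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def roc_auc(scores: Sequence[float], labels: Sequence[int]):
    """Stepwise ROC curve and AUC via a sorted sweep.

    AUC equals the Mann–Whitney probability P(score+ > score-) + 0.5 P(tie);
    tied scores are grouped so the curve takes the diagonal through tie
    blocks (trapezoidal area).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ConfigError("ROC requires at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos = (labels[order] == 1).astype(float)
    neg = 1.0 - pos
    # group tied scores: cumulative counts at the end of each tie block
    distinct = np.flatnonzero(np.diff(s) != 0)
    ends = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(pos)[ends]
    fp = np.cumsum(neg)[ends]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def accuracy_at_half(scores: np.ndarray, labels: np.ndarray) -> float:
    return float(((np.asarray(scores) >= 0.5).astype(int) == np.asarray(labels)).mean())


# --------------------------------------------------------------------------
# Repeated stratified CV
# --------------------------------------------------------------------------

# pipeline contract: (X_train, y_train, X_val, rng) -> scores for X_val
Pipeline = Callable[[np.ndarray, np.ndarray, np.ndarray, np.random.Generator], np.ndarray]


def make_smote_gbt_pipeline(
    resample: ResampleConfig | None,
    clf_config: ClassifierConfig,
    categorical_idx: Sequence[int] = (),
) -> Pipeline:
    """The study pipeline: rebalance the training fold, fit GBT, score."""

    def run(X_tr, y_tr, X_val, rng):
        if resample is not None:
            rs = smote_enn(X_tr, y_tr, resample, categorical_idx, rng=rng)
            X_fit, y_fit = rs.X, rs.y
        else:
            X_fit, y_fit = X_tr, y_tr
        cfg = ClassifierConfig(
            n_estimators=clf_config.n_estimators,
            num_leaves=clf_config.num_leaves,
            class_weight=clf_config.class_weight,
            seed=int(rng.integers(2**31 - 1)),
        )
        clf = train_classifier(X_fit, y_fit, cfg)
        return clf.predict_proba(np.asarray(X_val, dtype=float))[:, 1]

    return run


@dataclass
class CVReport:
    runs: pd.DataFrame                       # dataset, repeat, fold, auc, accuracy
    curves: list[dict] = field(default_factory=list)

    def summary(self, per_dataset: bool = False):
        def agg(sub: pd.DataFrame) -> dict:
            out = {}
            for metric in ("auc", "accuracy"):
                vals = sub[metric].to_numpy()
                mean = float(vals.mean())
                sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
                out[metric] = {
                    "mean": mean, "sd": sd,
                    "ci95": [mean - 1.96 * sd, mean + 1.96 * sd],
                    "n_runs": int(len(vals)),
                }
            return out

        if per_dataset:
            return {ds: agg(sub) for ds, sub in self.runs.groupby("dataset")}
        return agg(self.runs)


def repeated_stratified_cv(
    datasets: Mapping[str, np.ndarray],
    y: np.ndarray,
    cv: CVConfig,
    pipeline: Pipeline,
    keep_curves: bool = False,
) -> CVReport:
    """n_repeats independent stratified shuffles x n_splits folds per dataset.

    All datasets must share ``y`` and row order, so every dataset sees
    identical fold assignments for a given repeat.  Resampling (if any)
    happens inside the pipeline on the training fold only.
    """
    y = np.asarray(y)
    n_min = min(np.bincount(y).min(), len(y))
    if n_min < cv.n_splits:
        raise ConfigError(
            f"minority class count {n_min} < n_splits {cv.n_splits}: "
            "stratification cannot give both classes to every fold"
        )
    seed_seq = np.random.SeedSequence(cv.seed)
    fold_seeds = seed_seq.spawn(cv.n_repeats)
    rows = []
    curves: list[dict] = []
    for ds_id, X in datasets.items():
        X = np.asarray(X, dtype=float)
        for rep, fs in enumerate(fold_seeds):
            rep_rng = np.random.default_rng(fs)
            skf = StratifiedKFold(
                n_splits=cv.n_splits, shuffle=True,
                random_state=int(rep_rng.integers(2**31 - 1)),
            )
            for fold, (tr, va) in enumerate(skf.split(X, y)):
                scores = pipeline(X[tr], y[tr], X[va], rep_rng)
                fpr, tpr, auc = roc_auc(scores, y[va])
                acc = accuracy_at_half(scores, y[va])
                rows.append((ds_id, rep, fold, auc, acc))
                if keep_curves:
                    curves.append({"dataset": ds_id, "repeat": rep, "fold": fold,
                                   "fpr": fpr, "tpr": tpr})
    runs = pd.DataFrame(rows, columns=["dataset", "repeat", "fold", "auc", "accuracy"])
    return CVReport(runs=runs, curves=curves)
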