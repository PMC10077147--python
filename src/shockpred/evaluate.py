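"""Imputation-quality evaluation: KS grid with FDR correction.

For every variable that had missing cells, the values filled in at
initially-missing positions are compared against the initially observed
values with a two-sample Kolmogorov–Smirnov test, one test per (variable,
imputed dataset) cell.  p-values are corrected jointly across the whole
grid with the Benjamini–Yekutieli step-up procedure (valid under arbitrary
dependence), significance is annotated with stars, and marginal counts plus
a per-variable best-method choice summarize the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from .errors import ConfigError
from .impute.config import ImputationSet
from .matrix import CATEGORICAL, FeatureMatrix

METHOD_PREFERENCE = ("mice", "knn", "soft_impute", "iterative_svd")


# --------------------------------------------------------------------------
# Kolmogorov-Smirnov
# --------------------------------------------------------------------------

def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """sup_x |F_a(x) - F_b(x)| over the empirical CDFs."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / a.size
    fb = np.searchsorted(b, grid, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def ks_two_sample(
    a: Sequence[float],
    b: Sequence[float],
    permutation: int | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sample KS statistic and p-value.

    The p-value uses the asymptotic Kolmogorov distribution at
    sqrt(n_a n_b / (n_a + n_b)) * D.  Pass ``permutation=N`` for an exact-ish
    permutation p-value on small samples instead.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigError("KS test requires non-empty samples")
    d = ks_statistic(a, b)
    if permutation:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(permutation):
            perm = rng.permutation(pooled)
            if ks_statistic(perm[: a.size], perm[a.size:]) >= d - 1e-12:
                count += 1
        return d, (count + 1) / (permutation + 1)
    en = a.size * b.size / (a.size + b.size)
    p = float(special.kolmogorov(np.sqrt(en) * d))
    return d, min(max(p, 0.0), 1.0)


# --------------------------------------------------------------------------
# Benjamini-Yekutieli
# --------------------------------------------------------------------------

def by_adjust(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Yekutieli step-up adjustment.

    adj_(i) = min_{j >= i} min(1, p_(j) * m * c(m) / j) with
    c(m) = sum_{i=1..m} 1/i; rejects where adjusted p < q.  Returns
    ``(adjusted, reject)`` in the original order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    c_m = float(np.sum(1.0 / np.arange(1, m + 1)))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj, adj < q


def stars(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return ""


# --------------------------------------------------------------------------
# Report
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KSResult:
    variable: str
    dataset: str
    method: str
    D: float
    p_raw: float
    p_adj: float = float("nan")
    stars: str = ""


@dataclass
class EvalReport:
    results: list[KSResult]
    alpha: float
    skipped: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])

    def counts_per_dataset(self) -> pd.Series:
        df = self.to_frame()
        sig = df[df["p_adj"] < self.alpha]
        counts = sig.groupby("dataset").size()
        return counts.reindex(df["dataset"].unique(), fill_value=0)

    def counts_per_variable(self) -> pd.Series:
        df = self.to_frame()
        sig = df[df["p_adj"] < self.alpha]
        counts = sig.groupby("variable").size()
        return counts.reindex(df["variable"].unique(), fill_value=0)


def _categorical_encoding(
    observed: np.ndarray, levels: Sequence[str]
) -> dict[str, int]:
    """Integer codes ordered by observed frequency (desc), ties by level order."""
    counts = pd.Series(observed).value_counts()
    ordered = sorted(
        levels, key=lambda lev: (-int(counts.get(lev, 0)), list(levels).index(lev))
    )
    return {lev: i for i, lev in enumerate(ordered)}


def evaluate_imputation_set(
    original: FeatureMatrix,
    sets: Sequence[ImputationSet],
    alpha: float = 0.05,
    permutation: int | None = None,
) -> EvalReport:
    """KS grid of imputed-at-missing vs. initially observed values.

    The BY family is every (variable x dataset) cell jointly.  Variables
    with zero initially-missing cells are skipped (no test possible);
    categorical variables are tested on frequency-ordered integer encodings
    (logged caveat).
    """
    mask = original.mask
    results: list[KSResult] = []
    skipped: list[str] = []
    log: list[str] = []

    for name in original.variables:
        miss = mask[name].to_numpy()
        if not miss.any():
            skipped.append(name)
            log.append(f"skip {name}: no initially-missing cells")
            continue
        meta = original.meta_for(name)
        obs_vals = original.df.loc[~mask[name], name].to_numpy()
        if obs_vals.size == 0:
            skipped.append(name)
            log.append(f"skip {name}: no observed cells")
            continue
        if meta.vtype == CATEGORICAL:
            enc = _categorical_encoding(obs_vals, meta.levels or ())
            obs_num = np.array([enc[v] for v in obs_vals], dtype=float)
            log.append(f"caveat {name}: KS applied to frequency-ordered level codes")
        else:
            obs_num = obs_vals.astype(float)

        for imp_set in sets:
            for ds_id, completed in zip(imp_set.dataset_ids(), imp_set.matrices):
                imp_vals = completed.df.loc[miss, name].to_numpy()
                if meta.vtype == CATEGORICAL:
                    imp_num = np.array([enc[v] for v in imp_vals], dtype=float)
                else:
                    imp_num = imp_vals.astype(float)
                d, p = ks_two_sample(imp_num, obs_num, permutation=permutation)
                results.append(KSResult(
                    variable=name, dataset=ds_id, method=imp_set.method, D=d, p_raw=p,
                ))

    if results:
        adj, _ = by_adjust([r.p_raw for r in results], q=alpha)
        results = [
            KSResult(r.variable, r.dataset, r.method, r.D, r.p_raw,
                     float(a), stars(float(a)))
            for r, a in zip(results, adj)
        ]
    return EvalReport(results=results, alpha=alpha, skipped=skipped, log=log)


def count_significant(report: EvalReport, axis: str) -> pd.Series:
    if axis == "dataset":
        return report.counts_per_dataset()
    if axis == "variable":
        return report.counts_per_variable()
    raise ConfigError(f"axis must be 'dataset' or 'variable', got {axis!r}")


def select_best_method(report: EvalReport) -> pd.Series:
    """Per variable: method with the lowest mean D (MICE datasets averaged).

    Ties prefer MICE, then the fixed method order knn, soft_impute,
    iterative_svd.
    """
    df = report.to_frame()
    if df.empty:
        return pd.Series(dtype=object)
    mean_d = df.groupby(["variable", "method"])["D"].mean()
    choices = {}
    for var in df["variable"].unique():
        sub = mean_d.loc[var]
        best = min(
            sub.index,
            key=lambda meth: (sub[meth], METHOD_PREFERENCE.index(meth)
                              if meth in METHOD_PREFERENCE else len(METHOD_PREFERENCE)),
        )
        choices[var] = best
    return pd.Series(choices, name="selected_method").rename_axis("variable")


def write_report(report: EvalReport, outdir) -> None:
    """Tidy CSV outputs: grid, marginal counts, per-variable selection."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(outdir / "ks_grid.csv", index=False)
    report.counts_per_dataset().rename("n_significant").to_csv(
        outdir / "counts_per_dataset.csv")
    report.counts_per_variable().rename("n_significant").to_csv(
        outdir / "counts_per_variable.csv")
    select_best_method(report).to_csv(outdir / "selected_methods.csv")
    (outdir / "evaluation_log.txt").write_text("\n".join(report.log) + "\n")
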