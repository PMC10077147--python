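"""Optional figure outputs mirroring the evaluation report.

matplotlib is imported lazily so headless/report-only installs never touch
a plotting backend.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .evaluate import EvalReport
from .impute.config import ImputationSet
from .matrix import FeatureMatrix


def ks_heatmap(report: EvalReport, path: str | Path) -> None:
    """Variables x datasets heatmap of KS statistics with star annotations."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = report.to_frame()
    grid = frame.pivot(index="variable", columns="dataset", values="D")
    star_grid = frame.pivot(index="variable", columns="dataset", values="stars")
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * grid.shape[1], 1.0 + 0.35 * grid.shape[0]))
    im = ax.imshow(grid.to_numpy(), cmap="viridis", aspect="auto",
                   vmin=0.0, vmax=1.0)
    ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(grid.shape[0]), grid.index, fontsize=7)
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            s = star_grid.iloc[i, j]
            if s:
                ax.text(j, i, s, ha="center", va="center", color="white",
                        fontsize=6)
    fig.colorbar(im, ax=ax, label="KS statistic (lower is better)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def imputation_violins(
    original: FeatureMatrix,
    sets: list[ImputationSet],
    variable: str,
    path: str | Path,
) -> None:
    """Observed vs imputed vs all-data violins for one continuous variable."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    miss = original.mask[variable]
    observed = original.df.loc[~miss, variable].to_numpy(dtype=float)
    groups = [("observed", observed)]
    for imp_set in sets:
        for ds_id, completed in zip(imp_set.dataset_ids(), imp_set.matrices):
            imputed = completed.df.loc[miss, variable].to_numpy(dtype=float)
            if imputed.size:
                groups.append((ds_id, imputed))
    fig, ax = plt.subplots(figsize=(1.0 + 0.8 * len(groups), 4))
    ax.violinplot([g[1] for g in groups], showmedians=True)
    ax.set_xticks(np.arange(1, len(groups) + 1), [g[0] for g in groups],
                  rotation=90, fontsize=7)
    ax.set_title(variable)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
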