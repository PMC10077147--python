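"""Mixed-type subject x variable matrix with an explicit missingness mask.

The :class:`FeatureMatrix` is the common currency of the pipeline: the
synthetic generator emits one, cleaning reconstructs one from event tables,
the imputation engines complete one, and the evaluation / classification
stages consume them.  Values live in a :class:`pandas.DataFrame` (floats for
continuous variables, level strings for categoricals, NaN for missing); the
per-variable type metadata travels alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class VariableMeta:
    """Type metadata for one aggregated variable (column)."""

    name: str
    vtype: str
    unit: str | None = None
    levels: tuple[str, ...] | None = None
    role: str = "model"  # "model" | "expansion" (imputation-only, dropped at restriction)

    def __post_init__(self) -> None:
        if self.vtype not in (CONTINUOUS, CATEGORICAL):
            raise ConfigError(f"unknown vtype {self.vtype!r} for variable {self.name!r}")
        if self.vtype == CATEGORICAL and not self.levels:
            raise ConfigError(f"categorical variable {self.name!r} needs levels")


class FeatureMatrix:
    """Subjects x mixed-type variables with missingness mask.

    Parameters
    ----------
    df
        Values; index identifies the subject/stay, one column per variable.
        Continuous columns are float (NaN = missing); categorical columns hold
        level strings (NaN = missing).
    meta
        One :class:`VariableMeta` per column, in column order.
    """

    def __init__(self, df: pd.DataFrame, meta: Sequence[VariableMeta]):
        meta = tuple(meta)
        names = [m.name for m in meta]
        if list(df.columns) != names:
            raise ConfigError(
                f"column/metadata mismatch: {list(df.columns)} vs {names}"
            )
        df = df.copy()
        for m in meta:
            if m.vtype == CONTINUOUS:
                df[m.name] = pd.to_numeric(df[m.name], errors="coerce").astype(float)
            else:
                col = df[m.name].astype(object)
                known = set(m.levels or ())
                bad = {v for v in col.dropna().unique() if v not in known}
                if bad:
                    raise ConfigError(
                        f"unknown levels {sorted(map(str, bad))} in categorical "
                        f"variable {m.name!r}"
                    )
                df[m.name] = col
        self.df = df
        self.meta = meta
        self._by_name = {m.name: m for m in meta}

    # -- basic accessors -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    @property
    def variables(self) -> list[str]:
        return list(self.df.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the cell is missing."""
        return self.df.isna()

    def meta_for(self, name: str) -> VariableMeta:
        return self._by_name[name]

    def continuous_names(self) -> list[str]:
        return [m.name for m in self.meta if m.vtype == CONTINUOUS]

    def categorical_names(self) -> list[str]:
        return [m.name for m in self.meta if m.vtype == CATEGORICAL]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.df.copy(), self.meta)

    def select(self, names: Iterable[str]) -> "FeatureMatrix":
        names = list(names)
        return FeatureMatrix(self.df[names].copy(), [self._by_name[n] for n in names])

    def loc_rows(self, index) -> "FeatureMatrix":
        return FeatureMatrix(self.df.loc[index].copy(), self.meta)

    def equals(self, other: "FeatureMatrix") -> bool:
        return self.meta == other.meta and self.df.equals(other.df)

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        path = Path(path)
        self.df.to_csv(path, index_label="subject_id")
        if meta_path is None:
            meta_path = path.with_suffix(".meta.json")
        records = [
            {
                "name": m.name,
                "vtype": m.vtype,
                "unit": m.unit,
                "levels": list(m.levels) if m.levels else None,
                "role": m.role,
            }
            for m in self.meta
        ]
        Path(meta_path).write_text(json.dumps(records, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, meta_path: str | Path | None = None) -> "FeatureMatrix":
        path = Path(path)
        if meta_path is None:
            meta_path = path.with_suffix(".meta.json")
        records = json.loads(Path(meta_path).read_text())
        meta = [
            VariableMeta(
                name=r["name"],
                vtype=r["vtype"],
                unit=r.get("unit"),
                levels=tuple(r["levels"]) if r.get("levels") else None,
                role=r.get("role", "model"),
            )
            for r in records
        ]
        df = pd.read_csv(path, index_col="subject_id")
        return cls(df[[m.name for m in meta]], meta)


def missingness_profile(matrix: FeatureMatrix) -> tuple[pd.Series, float]:
    """Per-variable and overall missing fractions.

    Returns ``(per_variable, overall)`` where ``per_variable`` maps each
    column to ``missing cells / rows`` and ``overall`` is
    ``missing cells / total cells``.
    """
    n_rows, n_cols = matrix.shape
    if n_rows == 0 or n_cols == 0:
        raise ConfigError("cannot profile an empty matrix")
    mask = matrix.mask
    per_var = mask.mean(axis=0)
    overall = float(mask.to_numpy().sum()) / (n_rows * n_cols)
    return per_var, overall


def assert_observed_preserved(
    original: FeatureMatrix, completed: FeatureMatrix
) -> None:
    """Raise AssertionError unless completed == original wherever observed."""
    mask = original.mask
    for name in original.variables:
        obs = ~mask[name]
        a = original.df.loc[obs, name].to_numpy()
        b = completed.df.loc[obs, name].to_numpy()
        if original.meta_for(name).vtype == CONTINUOUS:
            if not np.array_equal(a.astype(float), b.astype(float)):
                raise AssertionError(f"observed cells of {name!r} changed")
        else:
            if not all(x == y for x, y in zip(a, b)):
                raise AssertionError(f"observed cells of {name!r} changed")
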