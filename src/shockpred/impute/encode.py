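"""Numeric encoding of mixed-type matrices for matrix-completion methods.

Continuous columns are z-scored on their observed cells; categoricals become
one-hot blocks whose rows are blank (NaN) where the cell is missing.  The
decoder inverts the map (argmax over each one-hot block) and restores
observed cells exactly from the source matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..matrix import CATEGORICAL, CONTINUOUS, FeatureMatrix


@dataclass
class _ColumnCodec:
    name: str
    vtype: str
    cols: slice                 # columns of this variable in the numeric matrix
    mean: float = 0.0
    sd: float = 1.0
    levels: tuple[str, ...] = ()


class MixedDecoder:
    def __init__(self, source: FeatureMatrix, codecs: list[_ColumnCodec], n_cols: int):
        self._source = source
        self._codecs = codecs
        self.n_cols = n_cols

    def decode(self, numeric: np.ndarray, restore_observed: bool = True) -> FeatureMatrix:
        """Map a completed numeric matrix back to mixed types.

        ``restore_observed`` copies originally observed cells verbatim from
        the source matrix (exact round trip, the contract every completion
        engine promises).
        """
        src = self._source
        out = src.df.copy()
        for c in self._codecs:
            block = numeric[:, c.cols]
            if c.vtype == CONTINUOUS:
                vals = block[:, 0] * c.sd + c.mean
                out[c.name] = vals
            else:
                idx = np.nanargmax(np.nan_to_num(block, nan=-np.inf), axis=1)
                out[c.name] = np.asarray(c.levels, dtype=object)[idx]
        if restore_observed:
            obs = ~src.mask
            for name in src.variables:
                sel = obs[name].to_numpy()
                out.loc[sel, name] = src.df.loc[sel, name]
        return FeatureMatrix(out, src.meta)


def encode_mixed(
    matrix: FeatureMatrix, center: bool = True
) -> tuple[np.ndarray, MixedDecoder]:
    """Return ``(numeric matrix with NaN for missing, decoder)``.

    With ``center=True`` continuous columns are z-scored on their observed
    cells.  ``center=False`` scales by the observed SD but keeps the offset:
    diagonal column scaling preserves matrix rank exactly, which the
    low-rank completion engines rely on (mean-centering would inflate the
    rank of an exactly low-rank matrix).

    Single-level categoricals carry no information for completion and are
    dropped from the numeric view with a warning (the decoder still restores
    them from the source).
    """
    n = len(matrix.df)
    blocks: list[np.ndarray] = []
    codecs: list[_ColumnCodec] = []
    col = 0
    for m in matrix.meta:
        series = matrix.df[m.name]
        if m.vtype == CONTINUOUS:
            vals = series.to_numpy(dtype=float)
            obs = ~np.isnan(vals)
            mean = float(np.mean(vals[obs])) if obs.any() else 0.0
            sd = float(np.std(vals[obs])) if obs.any() else 1.0
            if sd == 0.0:
                sd = 1.0
            if not center:
                mean = 0.0
            z = (vals - mean) / sd
            blocks.append(z[:, None])
            codecs.append(_ColumnCodec(m.name, CONTINUOUS, slice(col, col + 1), mean, sd))
            col += 1
        else:
            levels = tuple(m.levels or ())
            if len(levels) < 2:
                warnings.warn(
                    f"dropping single-level categorical {m.name!r} from numeric encoding"
                )
                continue
            onehot = np.full((n, len(levels)), np.nan)
            vals = series.to_numpy(dtype=object)
            for j, lev in enumerate(levels):
                known = pd.notna(vals)
                onehot[known, j] = (vals[known] == lev).astype(float)
            blocks.append(onehot)
            codecs.append(_ColumnCodec(
                m.name, CATEGORICAL, slice(col, col + len(levels)), levels=levels
            ))
            col += len(levels)
    numeric = np.hstack(blocks) if blocks else np.empty((n, 0))
    return numeric, MixedDecoder(matrix, codecs, col)
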