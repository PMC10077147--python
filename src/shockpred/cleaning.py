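"""Coded cohort selection and event-table cleaning.

Covers: ICD-9 based strict/relaxed cohort rules, clustering of multiple
source item codes into aggregated variables with first-recorded selection,
unit standardization, decimal-shift repair, implausible-value deletion, and
missingness profiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError
from .matrix import CATEGORICAL, CONTINUOUS, FeatureMatrix, VariableMeta
from .matrix import missingness_profile  # re-exported: part of this module's surface

__all__ = [
    "CohortSpec", "VariableCluster", "expand_icd9_range", "normalize_icd9",
    "select_cohort", "convert_unit", "register_conversion", "repair_or_drop",
    "aggregate_first_recorded", "clean_matrix", "missingness_profile",
    "default_cohort_spec", "default_clusters", "DEFAULT_RANGES",
]

PATIENT, CONTROL, EXCLUDED = "patient", "control", "excluded"


# --------------------------------------------------------------------------
# ICD-9 handling
# --------------------------------------------------------------------------

def normalize_icd9(code: object, context: str = "") -> str:
    """Strip/zero-pad an ICD-9 code; reject non-numeric codes with context."""
    s = str(code).strip().replace(".", "")
    if not s.isdigit():
        raise ParseError(f"non-numeric ICD-9 code {code!r}{context}")
    return s.zfill(5)


def expand_icd9_range(lo: str, hi: str) -> tuple[str, ...]:
    """Expand a printed range like 41000-41092 on zero-padded 5-char codes."""
    lo_i, hi_i = int(lo), int(hi)
    if lo_i > hi_i:
        raise ConfigError(f"bad ICD-9 range {lo}-{hi}")
    return tuple(str(c).zfill(5) for c in range(lo_i, hi_i + 1))


@dataclass(frozen=True)
class CohortSpec:
    """Strict/relaxed coded inclusion rules.

    ``patient_only_dx`` identifies the positive class (shock codes);
    ``shared_dx`` are diagnoses both groups may carry; ``required_procedures``
    gate strict inclusion (catheterization codes).
    """

    patient_only_dx: frozenset[str]
    shared_dx: frozenset[str]
    required_procedures: frozenset[str]
    mode: str = "strict"

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "relaxed"):
            raise ConfigError(f"unknown cohort mode {self.mode!r}")
        if self.patient_only_dx & self.shared_dx:
            raise ConfigError("patient_only_dx and shared_dx overlap")
        if self.mode == "strict" and not self.required_procedures:
            raise ConfigError("strict mode requires at least one procedure code")


def default_cohort_spec(mode: str = "strict") -> CohortSpec:
    """Shock dx vs. MI/IHD/angina shared dx with catheterization procedures."""
    shared = set(expand_icd9_range("41000", "41092")) | {"41189", "4139"}
    return CohortSpec(
        patient_only_dx=frozenset({"78551", "78550"}),
        shared_dx=frozenset(shared),
        required_procedures=frozenset(
            {"0066", "3604", "3606", "3607", "3609",
             "8855", "8856", "8857", "3722", "3723"}
        ),
        mode=mode,
    )


def _code_sets(table: pd.DataFrame, context: str) -> pd.Series:
    codes = table["icd9_code"].map(
        lambda c: normalize_icd9(c, context=f" in {context} table")
    )
    return codes.groupby(table["subject_id"]).agg(set)


def select_cohort(
    diagnoses: pd.DataFrame,
    procedures: pd.DataFrame,
    spec: CohortSpec,
) -> pd.Series:
    """Assign each subject exactly one of {patient, control, excluded}.

    Strict: patient = >=1 patient-only dx AND >=1 required procedure;
    control = >=1 shared dx AND >=1 required procedure AND no patient-only dx;
    everyone else excluded.  Relaxed: >=1 dx from the union qualifies,
    procedures ignored (group split kept for bookkeeping).
    """
    pat = frozenset(normalize_icd9(c) for c in spec.patient_only_dx)
    shr = frozenset(normalize_icd9(c) for c in spec.shared_dx)
    prc = frozenset(normalize_icd9(c) for c in spec.required_procedures)

    dx_sets = _code_sets(diagnoses, "diagnosis")
    proc_sets = _code_sets(procedures, "procedure") if len(procedures) else pd.Series(dtype=object)

    subjects = sorted(set(dx_sets.index) | set(proc_sets.index))
    out = {}
    for sid in subjects:
        dx = dx_sets.get(sid, set())
        pr = proc_sets.get(sid, set())
        has_pat = bool(dx & pat)
        has_shared = bool(dx & shr)
        has_proc = bool(pr & prc)
        if spec.mode == "relaxed":
            if has_pat:
                out[sid] = PATIENT
            elif has_shared:
                out[sid] = CONTROL
            else:
                out[sid] = EXCLUDED
        else:
            if has_pat and has_proc:
                out[sid] = PATIENT
            elif has_shared and has_proc and not has_pat:
                out[sid] = CONTROL
            else:
                out[sid] = EXCLUDED
    return pd.Series(out, name="group").rename_axis("subject_id")


# --------------------------------------------------------------------------
# Unit conversion
# --------------------------------------------------------------------------

def _norm_unit(u: str) -> str:
    return str(u).strip().lower().replace("\N{DEGREE SIGN}", "").replace("deg", "").strip()


_CONVERSIONS: dict[tuple[str, str], Callable[[float], float]] = {
    ("f", "c"): lambda v: (v - 32.0) * 5.0 / 9.0,
    ("c", "f"): lambda v: v * 9.0 / 5.0 + 32.0,
    ("lb", "kg"): lambda v: v * 0.45359237,
    ("lbs", "kg"): lambda v: v * 0.45359237,
    ("in", "cm"): lambda v: v * 2.54,
    ("mmhg", "kpa"): lambda v: v * 0.133322,
}


def register_conversion(from_unit: str, to_unit: str, fn: Callable[[float], float]) -> None:
    _CONVERSIONS[(_norm_unit(from_unit), _norm_unit(to_unit))] = fn


def convert_unit(value: float, from_unit: str, to_unit: str) -> float:
    f, t = _norm_unit(from_unit), _norm_unit(to_unit)
    if f == t:
        return value
    fn = _CONVERSIONS.get((f, t))
    if fn is None:
        known = ", ".join(f"{a}->{b}" for a, b in sorted(_CONVERSIONS))
        raise ConfigError(
            f"no registered conversion {from_unit!r} -> {to_unit!r}; known: {known}"
        )
    return fn(value)


# --------------------------------------------------------------------------
# Variable clusters, repair, aggregation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableCluster:
    """Aggregation rule: several source item codes -> one variable."""

    target: str
    codes: tuple[str, ...]
    vtype: str = CONTINUOUS
    unit: str | None = None                        # standard/target unit
    code_units: Mapping[str, str] = field(default_factory=dict)  # per-code source unit
    plausible_range: tuple[float, float] | None = None  # soft, decimal-repair window
    hard_range: tuple[float, float] | None = None       # deletion bounds
    levels: tuple[str, ...] | None = None
    role: str = "model"

    def __post_init__(self) -> None:
        if not self.codes:
            raise ConfigError(f"cluster {self.target!r} has no source codes")
        for rng in (self.plausible_range, self.hard_range):
            if rng is not None and not rng[0] < rng[1]:
                raise ConfigError(f"cluster {self.target!r}: range lo must be < hi")

    def meta(self) -> VariableMeta:
        return VariableMeta(name=self.target, vtype=self.vtype, unit=self.unit,
                            levels=self.levels, role=self.role)


# Hard/plausible ranges for the model variables.  Only the temperature pair is
# sourced from the documented repair examples; the rest are implementer
# defaults and overridable through the cluster config.
DEFAULT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "heart_rate": {"plausible": (20, 250), "hard": (10, 350)},
    "respiratory_rate": {"plausible": (4, 60), "hard": (0, 100)},
    "spo2": {"plausible": (50, 100), "hard": (0, 100)},
    "glucose": {"plausible": (30, 1000), "hard": (10, 2500)},
    "systolic_bp": {"plausible": (50, 260), "hard": (20, 400)},
    "age": {"plausible": (18, 100), "hard": (0, 120)},
    "o2_flow": {"plausible": (0.5, 60), "hard": (-1, 100)},
    "temperature": {"plausible": (30, 43), "hard": (25, 45)},
}


def default_clusters(
    code_map: Mapping[str, Sequence[str]],
    metas: Sequence[VariableMeta],
) -> list[VariableCluster]:
    """Build clusters matching a synthetic code map (ranges from defaults)."""
    clusters = []
    for m in metas:
        ranges = DEFAULT_RANGES.get(m.name, {})
        clusters.append(VariableCluster(
            target=m.name,
            codes=tuple(code_map[m.name]),
            vtype=m.vtype,
            unit=m.unit,
            plausible_range=ranges.get("plausible"),
            hard_range=ranges.get("hard"),
            levels=m.levels,
            role=m.role,
        ))
    return clusters


def repair_or_drop(value: float, cluster: VariableCluster) -> tuple[float, str]:
    """Decimal-shift repair / implausible-value deletion for one numeric value.

    Returns ``(new_value, action)`` with action in {kept, repaired, deleted}.
    A value is shifted down by a factor of 10 when the shifted value lands in
    the plausible range while the original is outside the hard range; values
    outside the hard range otherwise are deleted (NaN).
    """
    if cluster.hard_range is None:
        return value, "kept"
    lo, hi = cluster.hard_range
    in_hard = lo <= value <= hi
    if cluster.plausible_range is not None and not in_hard:
        plo, phi = cluster.plausible_range
        if plo <= value / 10.0 <= phi:
            return value / 10.0, "repaired"
    if not in_hard:
        return math.nan, "deleted"
    return value, "kept"


def _code_to_cluster(clusters: Sequence[VariableCluster]) -> dict[str, VariableCluster]:
    mapping: dict[str, VariableCluster] = {}
    for cl in clusters:
        for code in cl.codes:
            if code in mapping:
                raise ConfigError(
                    f"source code {code!r} appears in clusters "
                    f"{mapping[code].target!r} and {cl.target!r}"
                )
            mapping[code] = cl
    return mapping


def aggregate_first_recorded(
    events: pd.DataFrame,
    clusters: Sequence[VariableCluster],
    subjects: Iterable | None = None,
) -> FeatureMatrix:
    """First-recorded selection per (subject, cluster) with unit conversion.

    Each cell becomes the value of the earliest-timestamped event among the
    cluster's source codes; timestamp ties break lexicographically on the
    source code.  Events under codes not claimed by any cluster are ignored.
    """
    code_map = _code_to_cluster(clusters)
    ev = events.loc[events["item_code"].isin(code_map.keys())].copy()
    ev["charttime"] = pd.to_datetime(ev["charttime"])
    ev["_target"] = ev["item_code"].map(lambda c: code_map[c].target)
    ev = ev.sort_values(
        ["subject_id", "_target", "charttime", "item_code"], kind="mergesort"
    )
    first = ev.groupby(["subject_id", "_target"], sort=True).first()

    if subjects is None:
        subjects = sorted(events["subject_id"].unique())
    index = pd.Index(list(subjects), name="subject_id")

    data = {}
    for cl in clusters:
        col = pd.Series(np.nan, index=index, dtype=object)
        try:
            sub = first.xs(cl.target, level="_target")
        except KeyError:
            sub = pd.DataFrame(columns=first.columns)
        for sid, row in sub.iterrows():
            if sid not in index:
                continue
            val = row["value"]
            if cl.vtype == CONTINUOUS:
                val = float(val)
                src_unit = cl.code_units.get(row["item_code"], row.get("unit", cl.unit))
                if cl.unit and src_unit and str(src_unit) != "":
                    val = convert_unit(val, str(src_unit), cl.unit)
            col.loc[sid] = val
        data[cl.target] = col
    df = pd.DataFrame(data, index=index)
    return FeatureMatrix(df, [cl.meta() for cl in clusters])


def clean_matrix(
    matrix: FeatureMatrix,
    clusters: Sequence[VariableCluster],
) -> tuple[FeatureMatrix, list[str]]:
    """Apply repair_or_drop to every continuous cell; return matrix + log.

    The log is line-oriented: one ``subject<TAB>variable<TAB>old -> new``
    entry per repair or deletion.  Idempotent: cleaning a cleaned matrix is
    a no-op.
    """
    by_target = {cl.target: cl for cl in clusters}
    out = matrix.df.copy()
    log: list[str] = []
    for name in matrix.continuous_names():
        cl = by_target.get(name)
        if cl is None or cl.hard_range is None:
            continue
        col = out[name].to_numpy(dtype=float)
        for i, v in enumerate(col):
            if np.isnan(v):
                continue
            new, action = repair_or_drop(float(v), cl)
            if action != "kept":
                sid = out.index[i]
                shown = "missing" if math.isnan(new) else f"{new:g}"
                log.append(f"{sid}\t{name}\t{action}\t{v:g} -> {shown}")
                col[i] = new
        out[name] = col
    return FeatureMatrix(out, matrix.meta), log
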