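"""Synthetic coded-EHR cohort generator.

Emulates the structure the downstream pipeline assumes: a long-format event
table where each clinical variable is recorded under several source item
codes, ICD-9 coded diagnosis/procedure tables for cohort selection, mixed
continuous/categorical variables with per-class distribution parameters, a
heavy (~1:17) class imbalance, and per-variable MCAR missingness — all
reproducible from a single master seed.

Default parameters ship for the nine model variables (per-class means/SDs
and category frequencies, plus per-variable missing rates); the O2-flow
variable is a two-component Gaussian mixture so multimodal behaviour is
exercised.

Seed derivation: the master seed feeds a ``numpy.random.SeedSequence``;
child streams are spawned in a fixed, documented order (values, events,
masking), so every operation is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from .errors import ConfigError
from .matrix import CATEGORICAL, CONTINUOUS, FeatureMatrix, VariableMeta

_TOL = 1e-12


@dataclass(frozen=True)
class MixtureParams:
    """Gaussian-mixture parameters for one class of a continuous variable."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise ConfigError("mixture component lengths differ")
        if abs(sum(self.weights) - 1.0) > _TOL:
            raise ConfigError(f"mixture weights sum to {sum(self.weights)}, not 1")
        if any(w < 0 for w in self.weights):
            raise ConfigError("negative mixture weight")
        if any(s <= 0 for s in self.sds):
            raise ConfigError("mixture SDs must be > 0")

    @classmethod
    def single(cls, mean: float, sd: float) -> "MixtureParams":
        return cls(weights=(1.0,), means=(mean,), sds=(sd,))


@dataclass(frozen=True)
class CategoricalParams:
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.probs) - 1.0) > _TOL:
            raise ConfigError(f"categorical probabilities sum to {sum(self.probs)}, not 1")
        if any(p < 0 for p in self.probs):
            raise ConfigError("negative categorical probability")

    @classmethod
    def normalized(cls, probs: Sequence[float]) -> "CategoricalParams":
        total = float(sum(probs))
        return cls(probs=tuple(p / total for p in probs))


@dataclass(frozen=True)
class VariableSpec:
    """Generative spec for one clinical variable.

    ``class0_params``/``class1_params`` are :class:`MixtureParams` for
    continuous variables and :class:`CategoricalParams` for categoricals
    (probabilities aligned with ``levels``).
    """

    name: str
    vtype: str
    class0_params: MixtureParams | CategoricalParams
    class1_params: MixtureParams | CategoricalParams
    missing_rate: float = 0.0
    unit: str | None = None
    levels: tuple[str, ...] | None = None
    role: str = "model"

    def __post_init__(self) -> None:
        if self.vtype not in (CONTINUOUS, CATEGORICAL):
            raise ConfigError(f"unknown vtype {self.vtype!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError(f"missing_rate {self.missing_rate} outside [0, 1]")
        want = MixtureParams if self.vtype == CONTINUOUS else CategoricalParams
        for p in (self.class0_params, self.class1_params):
            if not isinstance(p, want):
                raise ConfigError(f"{self.name}: params type does not match vtype")
        if self.vtype == CATEGORICAL:
            if self.levels is None:
                raise ConfigError(f"{self.name}: categorical spec needs levels")
            for p in (self.class0_params, self.class1_params):
                if len(p.probs) != len(self.levels):
                    raise ConfigError(f"{self.name}: probs/levels length mismatch")

    def meta(self) -> VariableMeta:
        return VariableMeta(
            name=self.name, vtype=self.vtype, unit=self.unit,
            levels=self.levels, role=self.role,
        )


@dataclass
class CohortGenConfig:
    n_controls: int = 2130
    n_patients: int = 123
    variables: Sequence[VariableSpec] = field(default_factory=lambda: default_variable_specs())
    correlation: np.ndarray | None = None  # rank correlation across continuous vars
    n_relaxed_extra: int = 0  # control-like subjects meeting only relaxed criteria
    seed: int = 0

    def validate(self) -> None:
        if self.n_controls < 1 or self.n_patients < 1:
            raise ConfigError("n_controls and n_patients must both be >= 1")
        if self.n_relaxed_extra < 0:
            raise ConfigError("n_relaxed_extra must be >= 0")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate variable names")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            k = len([v for v in self.variables if v.vtype == CONTINUOUS])
            if c.shape != (k, k):
                raise ConfigError(
                    f"correlation must be {k}x{k} (one row per continuous variable)"
                )
            if not np.allclose(c, c.T, atol=1e-10):
                raise ConfigError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-10):
                raise ConfigError("correlation diagonal must be 1")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ConfigError("correlation matrix must be positive semi-definite")


def default_variable_specs() -> list[VariableSpec]:
    """Nine model variables plus one expansion-only variable.

    Continuous per-class (control / patient) means and SDs and categorical
    level frequencies follow the summary-statistics defaults this package
    ships; missing rates follow the per-variable default rates.
    """
    c = MixtureParams.single
    specs = [
        VariableSpec("heart_rate", CONTINUOUS, c(82.1, 16.343), c(94.1, 18.912),
                     missing_rate=0.0289, unit="bpm"),
        VariableSpec("respiratory_rate", CONTINUOUS, c(17.1, 5.549), c(20.1, 5.917),
                     missing_rate=0.027, unit="bpm"),
        VariableSpec("spo2", CONTINUOUS, c(97.8, 3.037), c(96.3, 4.699),
                     missing_rate=0.0344, unit="%"),
        VariableSpec("glucose", CONTINUOUS, c(157.8, 80.429), c(227.5, 135.491),
                     missing_rate=0.0187, unit="mg/dl"),
        VariableSpec("systolic_bp", CONTINUOUS, c(125.6, 24.112), c(108.9, 20.538),
                     missing_rate=0.3066, unit="mmHg"),
        VariableSpec("age", CONTINUOUS, c(67.0, 12.401), c(71.0, 11.997),
                     missing_rate=0.235, unit="y"),
        # bimodal: low-flow nasal cannula vs high-flow mask regime (invented params)
        VariableSpec(
            "o2_flow", CONTINUOUS,
            MixtureParams(weights=(0.7, 0.3), means=(2.0, 10.0), sds=(0.8, 2.0)),
            MixtureParams(weights=(0.35, 0.65), means=(2.5, 12.0), sds=(1.0, 2.5)),
            missing_rate=0.1238, unit="lpm",
        ),
        VariableSpec(
            "sex", CATEGORICAL,
            CategoricalParams.normalized((0.6446, 0.3554)),
            CategoricalParams.normalized((0.623, 0.377)),
            missing_rate=0.1774, levels=("male", "female"),
        ),
        VariableSpec(
            "ekg", CATEGORICAL,
            CategoricalParams.normalized((0.1761, 0.2485, 0.4718, 0.1036)),
            CategoricalParams.normalized((0.3279, 0.3115, 0.2869, 0.0738)),
            missing_rate=0.0,
            levels=("anterior_stemi_lbbb", "other_stemi", "nstemi", "other"),
        ),
        VariableSpec(
            "chf_history", CATEGORICAL,
            CategoricalParams.normalized((0.6432, 0.3568)),
            CategoricalParams.normalized((0.3279, 0.6721)),
            missing_rate=0.0, levels=("no", "yes"),
        ),
        # imputation-only expansion variable, dropped at the restriction step
        VariableSpec("temperature", CONTINUOUS, c(36.8, 0.7), c(36.9, 0.9),
                     missing_rate=0.0688, unit="degC", role="expansion"),
    ]
    return specs


# Each variable is stored in the event table under >=1 source item code;
# the first code is the "primary" one, extras mimic duplicate charting systems.
DEFAULT_CODE_MAP: dict[str, tuple[str, ...]] = {
    "heart_rate": ("HR", "HR_ALARM"),
    "respiratory_rate": ("RESP_RATE",),
    "spo2": ("SPO2", "SPO2_PLETH"),
    "glucose": ("GLUCOSE_LAB", "GLUCOSE_FS"),
    "systolic_bp": ("NBP_SYS", "ABP_SYS", "MANUAL_BP_SYS"),
    "age": ("AGE",),
    "o2_flow": ("O2_FLOW",),
    "sex": ("SEX",),
    "ekg": ("EKG_CLASS",),
    "chf_history": ("CHF_HIST",),
    "temperature": ("TEMP_C",),
}

PATIENT_DX = "78551"          # cardiogenic shock
SHARED_DX = ("41001", "41071", "41189", "4139")
PROCEDURES = ("0066", "8855", "3722", "3607")
RELAXED_ONLY_DX = "4139"      # dx present, no procedure -> relaxed inclusion only


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Spawn ``n`` independent child streams from the master seed (fixed order)."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sample_mixture(
    params: MixtureParams, z: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-transform mixture sampling driven by standard normals ``z``.

    Component membership is drawn independently; within a component the
    provided normal deviate is used directly, so copula correlation on ``z``
    survives into the marginal.
    """
    n = len(z)
    comp = rng.choice(len(params.weights), size=n, p=np.asarray(params.weights))
    means = np.asarray(params.means)[comp]
    sds = np.asarray(params.sds)[comp]
    return means + sds * z


def generate_feature_matrix(
    config: CohortGenConfig,
) -> tuple[FeatureMatrix, np.ndarray, pd.DataFrame]:
    """Draw the complete (pre-masking) cohort.

    Returns ``(matrix, labels, truth)``: the feature matrix (no missing
    values), binary class labels (1 = patient), and the per-subject truth
    record (class + true value for every variable).
    """
    config.validate()
    rng_values, _, _ = _child_rngs(config.seed, 3)

    n0 = config.n_controls + config.n_relaxed_extra
    n1 = config.n_patients
    n = n0 + n1
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    subject_ids = np.arange(10_000, 10_000 + n)

    cont = [v for v in config.variables if v.vtype == CONTINUOUS]
    k = len(cont)
    if config.correlation is not None and k:
        corr = np.asarray(config.correlation, dtype=float)
        # nudge onto the PSD cone for the Cholesky-free sampling path
        evals, evecs = np.linalg.eigh(corr)
        root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
        z_all = rng_values.standard_normal((n, k)) @ root.T
    else:
        z_all = rng_values.standard_normal((n, k))

    data: dict[str, np.ndarray] = {}
    z_idx = 0
    for v in config.variables:
        mask1 = labels == 1
        if v.vtype == CONTINUOUS:
            z = z_all[:, z_idx]
            z_idx += 1
            vals = np.empty(n)
            vals[~mask1] = _sample_mixture(v.class0_params, z[~mask1], rng_values)
            vals[mask1] = _sample_mixture(v.class1_params, z[mask1], rng_values)
            data[v.name] = vals
        else:
            levels = np.asarray(v.levels, dtype=object)
            out = np.empty(n, dtype=object)
            out[~mask1] = levels[
                rng_values.choice(len(levels), size=int((~mask1).sum()),
                                  p=np.asarray(v.class0_params.probs))
            ]
            out[mask1] = levels[
                rng_values.choice(len(levels), size=int(mask1.sum()),
                                  p=np.asarray(v.class1_params.probs))
            ]
            data[v.name] = out

    df = pd.DataFrame(data, index=pd.Index(subject_ids, name="subject_id"))
    matrix = FeatureMatrix(df, [v.meta() for v in config.variables])

    truth = df.copy()
    truth.insert(0, "label", labels)
    return matrix, labels, truth


@dataclass
class SyntheticEHR:
    """Coded-table view of a generated cohort."""

    events: pd.DataFrame       # subject_id, stay_id, item_code, charttime, value, unit
    diagnoses: pd.DataFrame    # subject_id, icd9_code, type="diagnosis"
    procedures: pd.DataFrame   # subject_id, icd9_code, type="procedure"
    matrix: FeatureMatrix      # the feature matrix the events encode
    labels: np.ndarray
    truth: pd.DataFrame
    relaxed_only: np.ndarray   # subject ids included only under relaxed criteria


def generate_event_table(
    config: CohortGenConfig,
    code_map: Mapping[str, Sequence[str]] | None = None,
    matrix: FeatureMatrix | None = None,
    labels: np.ndarray | None = None,
) -> SyntheticEHR:
    """Emit long-format events plus coded diagnosis/procedure tables.

    Each observed cell of the feature matrix becomes >=1 event row; the
    earliest-timestamped event carries the true value (in the variable's
    standard unit), later events under alternative source codes carry
    perturbed re-measurements, so first-recorded aggregation reconstructs
    the matrix cell-for-cell.  Pass a pre-masked ``matrix`` to encode
    missingness as absent events.
    """
    config.validate()
    if code_map is None:
        code_map = {v.name: DEFAULT_CODE_MAP.get(v.name, (v.name.upper(),))
                    for v in config.variables}
    if not code_map:
        raise ConfigError("code_map must assign at least one source code per variable")
    for v in config.variables:
        if not code_map.get(v.name):
            raise ConfigError(f"code_map has no source code for variable {v.name!r}")

    _, rng_events, _ = _child_rngs(config.seed, 3)
    if matrix is None or labels is None:
        matrix, labels, truth = generate_feature_matrix(config)
    else:
        truth = matrix.df.copy()
        truth.insert(0, "label", labels)

    base = pd.Timestamp("2130-01-01 00:00:00")
    rows = []
    for i, (sid, row) in enumerate(matrix.df.iterrows()):
        stay_id = 200_000 + i
        for v in config.variables:
            val = row[v.name]
            if pd.isna(val):
                continue
            codes = list(code_map[v.name])
            n_extra = int(rng_events.integers(0, len(codes))) if len(codes) > 1 else 0
            # distinct minute offsets within a synthetic 48 h stay window
            offsets = rng_events.choice(48 * 60, size=1 + n_extra, replace=False)
            offsets.sort()
            use_codes = [codes[0]] + list(
                rng_events.choice(codes[1:], size=n_extra, replace=False)
            ) if n_extra else [codes[0]]
            for j, (off, code) in enumerate(zip(offsets, use_codes)):
                if j == 0:
                    value = val
                elif v.vtype == CONTINUOUS:
                    value = float(val) + float(rng_events.normal(0, 0.5))
                else:
                    value = val
                rows.append(
                    (sid, stay_id, code, (base + pd.Timedelta(minutes=int(off))).isoformat(),
                     value, v.unit or "")
                )
    events = pd.DataFrame(
        rows, columns=["subject_id", "stay_id", "item_code", "charttime", "value", "unit"]
    )

    n0 = config.n_controls
    nx = config.n_relaxed_extra
    dx_rows, proc_rows = [], []
    relaxed_only = []
    for i, sid in enumerate(matrix.df.index):
        label = labels[i]
        is_relaxed_extra = (label == 0) and (i >= n0)
        if is_relaxed_extra:
            dx_rows.append((sid, RELAXED_ONLY_DX, "diagnosis"))
            relaxed_only.append(sid)
            continue  # no procedure: excluded under strict criteria
        shared = SHARED_DX[int(rng_events.integers(len(SHARED_DX)))]
        dx_rows.append((sid, shared, "diagnosis"))
        if label == 1:
            dx_rows.append((sid, PATIENT_DX, "diagnosis"))
        proc = PROCEDURES[int(rng_events.integers(len(PROCEDURES)))]
        proc_rows.append((sid, proc, "procedure"))

    diagnoses = pd.DataFrame(dx_rows, columns=["subject_id", "icd9_code", "type"])
    procedures = pd.DataFrame(proc_rows, columns=["subject_id", "icd9_code", "type"])
    return SyntheticEHR(
        events=events, diagnoses=diagnoses, procedures=procedures,
        matrix=matrix, labels=labels, truth=truth,
        relaxed_only=np.asarray(relaxed_only),
    )


def apply_mcar(
    matrix: FeatureMatrix,
    rates: Mapping[str, float] | float,
    seed: int,
) -> FeatureMatrix:
    """Mask cells completely at random at per-variable ``rates``.

    ``rates`` may be a scalar (applied to every variable) or a mapping
    (absent variables get rate 0).  Masking is independent of values and
    labels; observed cells are untouched.
    """
    if np.isscalar(rates):
        rates = {name: float(rates) for name in matrix.variables}
    for name, r in rates.items():
        if not 0.0 <= float(r) <= 1.0:
            raise ConfigError(f"missing rate {r} for {name!r} outside [0, 1]")
    _, _, rng_mask = _child_rngs(seed, 3)
    out = matrix.df.copy()
    n = len(out)
    for name in matrix.variables:
        r = float(rates.get(name, 0.0))
        if r <= 0.0:
            continue
        drop = rng_mask.random(n) < r
        col = out[name].to_numpy(dtype=object if
                                 matrix.meta_for(name).vtype == CATEGORICAL else float)
        col[drop] = np.nan
        out[name] = col
    return FeatureMatrix(out, matrix.meta)


def default_missing_rates(config: CohortGenConfig) -> dict[str, float]:
    return {v.name: v.missing_rate for v in config.variables}
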