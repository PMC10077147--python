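import numpy as np
import pandas as pd
import pytest

from shockpred.matrix import FeatureMatrix, VariableMeta
from shockpred.synthetic import (
    CategoricalParams,
    CohortGenConfig,
    MixtureParams,
    VariableSpec,
    apply_mcar,
    default_missing_rates,
    generate_feature_matrix,
)


@pytest.fixture
def small_mixed_matrix() -> FeatureMatrix:
    """6x3 hand-built mixed matrix with known missing cells."""
    df = pd.DataFrame(
        {
            "hr": [80.0, np.nan, 95.0, 70.0, np.nan, 88.0],
            "sbp": [120.0, 130.0, np.nan, 110.0, 125.0, 118.0],
            "sex": ["male", "female", np.nan, "male", "female", "male"],
        },
        index=pd.Index([1, 2, 3, 4, 5, 6], name="subject_id"),
    )
    meta = [
        VariableMeta("hr", "continuous", unit="bpm"),
        VariableMeta("sbp", "continuous", unit="mmHg"),
        VariableMeta("sex", "categorical", levels=("male", "female")),
    ]
    return FeatureMatrix(df, meta)


def small_gen_config(n_controls=150, n_patients=40, seed=0, **kw) -> CohortGenConfig:
    return CohortGenConfig(n_controls=n_controls, n_patients=n_patients,
                           seed=seed, **kw)


@pytest.fixture
def small_cohort():
    cfg = small_gen_config(seed=11)
    matrix, labels, truth = generate_feature_matrix(cfg)
    return cfg, matrix, labels, truth


@pytest.fixture
def masked_cohort(small_cohort):
    cfg, matrix, labels, truth = small_cohort
    masked = apply_mcar(matrix, default_missing_rates(cfg), seed=cfg.seed)
    return cfg, masked, matrix, labels


def bimodal_matrix(n: int, seed: int) -> FeatureMatrix:
    """Bimodal target plus two informative continuous predictors.

    The predictors are noisy copies of the target, so chained-equation
    models can identify the mode a missing cell belongs to.
    """
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < 0.5
    target = np.where(comp, rng.normal(6.0, 1.0, n), rng.normal(0.0, 1.0, n))
    df = pd.DataFrame(
        {
            "target": target,
            "pred1": target + rng.normal(0.0, 1.0, n),
            "pred2": target + rng.normal(0.0, 2.0, n),
        },
        index=pd.Index(np.arange(n), name="subject_id"),
    )
    meta = [VariableMeta(c, "continuous") for c in df.columns]
    return FeatureMatrix(df, meta)
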