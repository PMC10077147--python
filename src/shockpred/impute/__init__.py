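"""Multivariate imputation engines.

Four engines behind one dispatch surface: chained equations with
tree-ensemble conditional models and predictive mean matching (stochastic,
m completed datasets), k-nearest-neighbour imputation, SoftImpute
(iterative soft-thresholded SVD) and IterativeSVD (iterative fixed-rank
completion).
"""

from .config import ImputationConfig, ImputationSet
from .encode import MixedDecoder, encode_mixed
from .knn import knn_impute
from .matrix_completion import iterative_svd_impute, soft_impute
from .mice import mice_impute, pmm_draw

__all__ = [
    "ImputationConfig", "ImputationSet", "encode_mixed", "MixedDecoder",
    "mice_impute", "pmm_draw", "knn_impute", "soft_impute",
    "iterative_svd_impute", "impute",
]


def impute(matrix, config: ImputationConfig) -> ImputationSet:
    """Dispatch to the configured engine."""
    fn = {
        "mice": mice_impute,
        "knn": knn_impute,
        "soft_impute": soft_impute,
        "iterative_svd": iterative_svd_impute,
    }[config.method]
    return fn(matrix, config)
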