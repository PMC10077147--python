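"""Imputation configuration and result containers."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

from ..errors import ConfigError
from ..matrix import FeatureMatrix

METHODS = ("mice", "knn", "soft_impute", "iterative_svd")


@dataclass
class ImputationConfig:
    method: str = "mice"
    m: int = 10                 # completed datasets (MICE only)
    max_iter: int = 5           # chained-equation sweeps / completion iterations
    pmm_k: int = 5              # PMM donor candidates
    knn_k: int = 5
    lam: float | None = None    # SoftImpute shrinkage; None -> holdout grid
    rank: int = 10              # IterativeSVD target rank
    tol: float = 1e-3           # relative-change convergence threshold
    model: str = "gbt"          # MICE conditional model: "gbt" | "linear"
    model_params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"unknown imputation method {self.method!r}")
        if self.m < 1:
            raise ConfigError("m must be >= 1")
        if self.pmm_k < 1 or self.knn_k < 1:
            raise ConfigError("pmm_k and knn_k must be >= 1")
        if self.lam is not None and self.lam < 0:
            raise ConfigError("lambda must be >= 0")
        if self.rank < 1:
            raise ConfigError("rank must be >= 1")
        if self.tol <= 0:
            raise ConfigError("tol must be > 0")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class ImputationSet:
    """A family of completed matrices with method/config provenance."""

    matrices: list[FeatureMatrix]
    method: str
    config: ImputationConfig
    log: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, m in enumerate(self.matrices):
            if m.mask.to_numpy().any():
                raise ConfigError(f"completed matrix {i} still has missing cells")

    def __len__(self) -> int:
        return len(self.matrices)

    def dataset_ids(self) -> list[str]:
        if len(self.matrices) > 1:
            return [f"{self.method}_{i}" for i in range(len(self.matrices))]
        return [self.method]
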