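"""End-to-end orchestration: simulate -> clean -> impute -> evaluate ->
restrict -> rebalance+train -> report.

Every stage writes plain CSV/JSON artifacts into the run directory and the
final manifest records the config hash, the seed derivation, and per-stage
row counts, so a run is replayable from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cleaning, synthetic
from .classify import (ClassifierConfig, CVConfig, bivariate_screen,
                       make_smote_gbt_pipeline, repeated_stratified_cv, shock_index)
from .errors import ConfigError
from .evaluate import evaluate_imputation_set, select_best_method, write_report
from .impute import ImputationConfig, ImputationSet, encode_mixed, impute
from .matrix import FeatureMatrix, missingness_profile
from .rebalance import ResampleConfig
from .synthetic import (CategoricalParams, CohortGenConfig, MixtureParams,
                        VariableSpec, default_variable_specs)


def variable_spec_from_dict(d: Mapping[str, Any]) -> VariableSpec:
    """Parse one entry of the config file's ``variables`` list."""
    vtype = d["vtype"]
    if vtype == "continuous":
        def parse(p):
            if "weights" in p:
                return MixtureParams(tuple(p["weights"]), tuple(p["means"]),
                                     tuple(p["sds"]))
            return MixtureParams.single(p["mean"], p["sd"])
        c0, c1 = parse(d["class0"]), parse(d["class1"])
        levels = None
    else:
        levels = tuple(d["levels"])
        c0 = CategoricalParams.normalized(d["class0"]["probs"])
        c1 = CategoricalParams.normalized(d["class1"]["probs"])
    return VariableSpec(
        name=d["name"], vtype=vtype, class0_params=c0, class1_params=c1,
        missing_rate=float(d.get("missing_rate", 0.0)),
        unit=d.get("unit"), levels=levels, role=d.get("role", "model"),
    )


@dataclass
class PipelineConfig:
    seed: int = 0
    n_controls: int = 2130
    n_patients: int = 123
    n_relaxed_extra: int = 50
    variables: Sequence[VariableSpec] | None = None
    cohort_mode: str = "strict"
    imputations: list[ImputationConfig] = field(default_factory=lambda: [
        ImputationConfig(method="mice", m=10),
        ImputationConfig(method="knn"),
        ImputationConfig(method="soft_impute", max_iter=100, tol=1e-4),
        ImputationConfig(method="iterative_svd", rank=5, max_iter=100, tol=1e-4),
    ])
    alpha: float = 0.05
    rebalance: ResampleConfig = field(default_factory=ResampleConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    cv: CVConfig = field(default_factory=CVConfig)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        cfg = cls()
        cfg.seed = int(d.get("seed", 0))
        syn = d.get("synthetic", {})
        cfg.n_controls = int(syn.get("n_controls", cfg.n_controls))
        cfg.n_patients = int(syn.get("n_patients", cfg.n_patients))
        cfg.n_relaxed_extra = int(syn.get("n_relaxed_extra", cfg.n_relaxed_extra))
        if "variables" in syn:
            cfg.variables = [variable_spec_from_dict(v) for v in syn["variables"]]
        cfg.cohort_mode = d.get("cohort", {}).get("mode", "strict")
        if "imputation" in d:
            cfg.imputations = [ImputationConfig(**entry) for entry in d["imputation"]]
        cfg.alpha = float(d.get("evaluation", {}).get("alpha", 0.05))
        if "rebalance" in d:
            cfg.rebalance = ResampleConfig(**d["rebalance"])
        if "classifier" in d:
            cfg.classifier = ClassifierConfig(**d["classifier"])
        if "cv" in d:
            cfg.cv = CVConfig(**d["cv"])
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def gen_config(self) -> CohortGenConfig:
        return CohortGenConfig(
            n_controls=self.n_controls, n_patients=self.n_patients,
            variables=list(self.variables) if self.variables else default_variable_specs(),
            n_relaxed_extra=self.n_relaxed_extra, seed=self.seed,
        )

    def hashable_dict(self) -> dict:
        d = {
            "seed": self.seed, "n_controls": self.n_controls,
            "n_patients": self.n_patients, "n_relaxed_extra": self.n_relaxed_extra,
            "cohort_mode": self.cohort_mode, "alpha": self.alpha,
            "imputations": [ic.to_dict() for ic in self.imputations],
            "rebalance": asdict(self.rebalance),
            "classifier": asdict(self.classifier),
            "cv": asdict(self.cv),
            "variables": "default" if self.variables is None else
                         [str(v) for v in self.variables],
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.hashable_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _seed_for(master: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big")


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    gen = cfg.gen_config()
    matrix, labels, truth = synthetic.generate_feature_matrix(gen)
    rates = synthetic.default_missing_rates(gen)
    masked = synthetic.apply_mcar(matrix, rates, seed=gen.seed)
    ehr = synthetic.generate_event_table(gen, matrix=masked, labels=labels)

    ehr.events.to_csv(outdir / "events.csv", index=False)
    ehr.diagnoses.to_csv(outdir / "diagnoses.csv", index=False)
    ehr.procedures.to_csv(outdir / "procedures.csv", index=False)
    truth.to_csv(outdir / "truth.csv", index_label="subject_id")
    matrix.to_csv(outdir / "matrix_complete.csv")
    return {"n_subjects": len(truth), "n_events": len(ehr.events),
            "n_relaxed_extra": len(ehr.relaxed_only)}


def stage_clean(cfg: PipelineConfig, outdir: Path) -> dict:
    events = pd.read_csv(outdir / "events.csv")
    diagnoses = pd.read_csv(outdir / "diagnoses.csv", dtype={"icd9_code": str})
    procedures = pd.read_csv(outdir / "procedures.csv", dtype={"icd9_code": str})

    strict = cleaning.select_cohort(diagnoses, procedures,
                                    cleaning.default_cohort_spec("strict"))
    relaxed = cleaning.select_cohort(diagnoses, procedures,
                                     cleaning.default_cohort_spec("relaxed"))
    groups = pd.DataFrame({"group_strict": strict, "group_relaxed": relaxed})
    groups.to_csv(outdir / "groups.csv")

    gen = cfg.gen_config()
    code_map = {v.name: synthetic.DEFAULT_CODE_MAP.get(v.name, (v.name.upper(),))
                for v in gen.variables}
    clusters = cleaning.default_clusters(code_map, [v.meta() for v in gen.variables])
    included = relaxed.index[relaxed != cleaning.EXCLUDED]
    agg = cleaning.aggregate_first_recorded(events, clusters, subjects=included)
    cleaned, log = cleaning.clean_matrix(agg, clusters)
    cleaned.to_csv(outdir / "matrix_preimpute.csv")
    (outdir / "cleaning_log.txt").write_text("\n".join(log) + ("\n" if log else ""))

    per_var, overall = missingness_profile(cleaned)
    per_var.rename("missing_fraction").to_csv(outdir / "missingness.csv")
    return {"n_rows": cleaned.shape[0], "n_vars": cleaned.shape[1],
            "overall_missing": overall, "n_repairs": len(log)}


def stage_impute(cfg: PipelineConfig, outdir: Path) -> dict:
    matrix = FeatureMatrix.from_csv(outdir / "matrix_preimpute.csv")
    imp_dir = outdir / "imputed"
    imp_dir.mkdir(exist_ok=True)
    manifest = []
    for ic in cfg.imputations:
        ic.seed = _seed_for(cfg.seed, f"impute:{ic.method}")
        result = impute(matrix, ic)
        for ds_id, completed in zip(result.dataset_ids(), result.matrices):
            completed.to_csv(imp_dir / f"{ds_id}.csv")
            manifest.append({"dataset": ds_id, "method": ic.method,
                             "config": ic.to_dict()})
        (imp_dir / f"{ic.method}_log.json").write_text(json.dumps(result.log, indent=2))
    (imp_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"n_datasets": len(manifest)}


def _load_imputed(outdir: Path) -> list[ImputationSet]:
    imp_dir = outdir / "imputed"
    manifest = json.loads((imp_dir / "manifest.json").read_text())
    by_method: dict[str, list] = {}
    for entry in manifest:
        by_method.setdefault(entry["method"], []).append(entry)
    sets = []
    for method, entries in by_method.items():
        matrices = [FeatureMatrix.from_csv(imp_dir / f"{e['dataset']}.csv")
                    for e in entries]
        ic = ImputationConfig(**entries[0]["config"])
        sets.append(ImputationSet(matrices, method, ic))
    return sets


def stage_evaluate(cfg: PipelineConfig, outdir: Path) -> dict:
    original = FeatureMatrix.from_csv(outdir / "matrix_preimpute.csv")
    sets = _load_imputed(outdir)
    report = evaluate_imputation_set(original, sets, alpha=cfg.alpha)
    write_report(report, outdir / "evaluation")
    return {"n_tests": len(report.results), "n_skipped": len(report.skipped)}


def _final_numeric(matrix: FeatureMatrix, subjects: pd.Index) -> np.ndarray:
    """Restrict to final cohort/variables, append shock index, encode numeric."""
    model_vars = [m.name for m in matrix.meta if m.role == "model"]
    sub = matrix.select(model_vars).loc_rows(subjects)
    X, _ = encode_mixed(sub)
    if {"heart_rate", "systolic_bp"} <= set(sub.variables):
        si = shock_index(sub.df["heart_rate"].to_numpy(dtype=float),
                         sub.df["systolic_bp"].to_numpy(dtype=float))
        si = np.nan_to_num(si, nan=0.0)
        X = np.column_stack([X, (si - si.mean()) / (si.std() or 1.0)])
    return X


def stage_train(cfg: PipelineConfig, outdir: Path) -> dict:
    groups = pd.read_csv(outdir / "groups.csv", index_col="subject_id")
    strict = groups["group_strict"]
    final_subjects = strict.index[strict != cleaning.EXCLUDED]
    y = (strict.loc[final_subjects] == cleaning.PATIENT).astype(int).to_numpy()

    sets = _load_imputed(outdir)
    mice_sets = [s for s in sets if s.method == "mice"] or sets
    datasets: dict[str, np.ndarray] = {}
    screen_rows = []
    for s in mice_sets:
        for ds_id, completed in zip(s.dataset_ids(), s.matrices):
            datasets[ds_id] = _final_numeric(completed, pd.Index(final_subjects))
    # bivariate screening on the first dataset, for the report
    first = mice_sets[0].matrices[0]
    model_vars = [m.name for m in first.meta if m.role == "model"]
    screen, skipped = bivariate_screen(
        first.select(model_vars).loc_rows(pd.Index(final_subjects)), y)
    pd.DataFrame([r.__dict__ for r in screen]).to_csv(
        outdir / "bivariate_screen.csv", index=False)

    cv_cfg = CVConfig(n_splits=cfg.cv.n_splits, n_repeats=cfg.cv.n_repeats,
                      seed=_seed_for(cfg.seed, "cv"))
    pipeline = make_smote_gbt_pipeline(cfg.rebalance, cfg.classifier)
    report = repeated_stratified_cv(datasets, y, cv_cfg, pipeline)
    report.runs.to_csv(outdir / "cv_runs.csv", index=False)
    summary = {"pooled": report.summary(),
               "per_dataset": report.summary(per_dataset=True)}
    (outdir / "cv_summary.json").write_text(json.dumps(summary, indent=2))
    return {"n_runs": len(report.runs), "n_final_subjects": int(len(y)),
            "mean_auc": summary["pooled"]["auc"]["mean"]}


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage and write the manifest; returns the artifact dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [
        ("simulate", stage_simulate),
        ("clean", stage_clean),
        ("impute", stage_impute),
        ("evaluate", stage_evaluate),
        ("train", stage_train),
    ]
    stage_info = {}
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            info = fn(cfg, outdir)
        except Exception as exc:
            raise ConfigError(f"stage {name!r} failed: {exc}") from exc
        info["seconds"] = round(time.perf_counter() - t0, 3)
        stage_info[name] = info
    manifest = {
        "config": cfg.hashable_dict(),
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.seed,
        "stages": stage_info,
        "artifacts": sorted(str(p.relative_to(outdir))
                            for p in outdir.rglob("*") if p.is_file()
                            and p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
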