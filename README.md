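# shockpred

EHR pre-processing and cardiogenic-shock prediction pipeline: ICD-9 coded
cohort selection, event-table cleaning, four multivariate missing-data
imputation engines, a KS/FDR imputation-quality evaluation framework, and
imbalance-aware gradient-boosted classification under repeated stratified
cross-validation — all exercisable end to end on a bundled synthetic-EHR
generator (no external data required).

## Modules

| module | what it does |
| --- | --- |
| `shockpred.synthetic` | Generates coded event tables, ICD-9 diagnosis/procedure tables, and mixed-type feature matrices with configurable per-class Gaussian-mixture / categorical parameters, a Gaussian-copula correlation option, ~1:17 class imbalance, and per-variable MCAR masking. |
| `shockpred.cleaning` | Strict/relaxed ICD-9 cohort rules (incl. numeric range expansion), clustering of multiple source item codes into aggregated variables with first-recorded selection, unit conversion (°F→°C etc.), decimal-shift repair (375 → 37.5), implausible-value deletion, missingness profiling. |
| `shockpred.impute` | Chained-equation imputation with gradient-boosted conditional models and 5-candidate predictive mean matching (m stochastic datasets), deterministic k-NN imputation, SoftImpute (iterative soft-thresholded SVD with warm-started λ continuation), IterativeSVD (fixed-rank completion), plus the mixed-type numeric encoder. |
| `shockpred.evaluate` | Per-(variable × dataset) two-sample Kolmogorov–Smirnov comparison of imputed vs originally observed values, Benjamini–Yekutieli FDR correction across the whole grid, star annotation, marginal significance counts, per-variable best-method selection. |
| `shockpred.rebalance` | SMOTE synthetic over-sampling followed by Edited-Nearest-Neighbours cleaning, with per-row provenance for leakage auditing. |
| `shockpred.classify` | Bivariate screening (chi-squared / t / Mann–Whitney), shock index, gradient-boosted classifier (100 estimators, 31 leaves, balanced class weights), in-repo ROC/AUC, repeated stratified K-fold CV with resampling inside training folds only. |
| `shockpred.pipeline` / `shockpred.cli` | Orchestration, YAML config, per-stage CSV/JSON artifacts, manifest with config hash and seeds. |

## CLI

```bash
# full pipeline on synthetic data (13 imputed datasets by default)
shockpred --seed 1 --outdir run1 run-all

# or stage by stage, with a config file
shockpred --config config.yaml --outdir run1 simulate
shockpred --config config.yaml --outdir run1 clean
shockpred --config config.yaml --outdir run1 impute
shockpred --config config.yaml --outdir run1 evaluate
shockpred --config config.yaml --outdir run1 train
```

Example `config.yaml`:

```yaml
seed: 1
synthetic:
  n_controls: 2130
  n_patients: 123
  n_relaxed_extra: 50
cohort: {mode: strict}
imputation:
  - {method: mice, m: 10}
  - {method: knn, knn_k: 5}
  - {method: soft_impute, max_iter: 100, tol: 1.0e-4}
  - {method: iterative_svd, rank: 5, max_iter: 100, tol: 1.0e-4}
evaluation: {alpha: 0.05}
rebalance: {smote_k: 5, target_ratio: 1.0, enn_k: 3}
classifier: {n_estimators: 100, num_leaves: 31, class_weight: balanced}
cv: {n_splits: 5, n_repeats: 50}
```

Artifacts written per run: event/diagnosis/procedure CSVs, the cleaned
pre-imputation matrix (+ metadata sidecar), one CSV per completed dataset,
the tidy KS grid and marginal-count CSVs, bivariate screening results,
per-run CV results with a JSON summary (mean/SD/95% CI for AUC and
accuracy), a line-oriented cleaning log, and a manifest with the config
hash — a run is replayable from its manifest alone.

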