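# vmec — multi-cohort vaginal-microbiome classification of endometrial cancer

Endometrial cancer (EC) is the most common gynecologic malignancy in
high-income countries and still lacks a minimally invasive rule-out test.
Several 16S rRNA case-control studies have linked the vaginal microbiome to
EC, but individual cohorts are small, batch-confounded, and report their
covariates inconsistently, so single-study classifiers generalize poorly.

`vmec` is an analysis pipeline for combining such cohorts. It provides:

* **Synthetic multi-cohort generation** (`vmec.simulate`) — a
  Dirichlet-multinomial generative model that reproduces the structure of a
  five-cohort EC case-control design (22/149/36/27/31 samples, 130 benign /
  135 EC), with cohort batch effects, higher alpha diversity and a
  *Peptoniphilus*-like enriched genus in EC, covariate effects
  (age/BMI/ethnicity/pH) on composition, and per-cohort covariate
  missingness (one cohort reports age only, one no metadata at all).
* **Ecology** (`vmec.ecology`) — Shannon diversity
  (H = −Σᵢ pᵢ ln pᵢ), Bray-Curtis / Jaccard / Jensen-Shannon /
  unweighted & weighted UniFrac distances, and marginal PERMANOVA on
  Gower-centered distance matrices with free-permutation p-values.
* **Differential abundance** (`vmec.diffabund`) — a bias-corrected
  log-linear model: per-sample offsets (log sampling fractions) estimated by
  robust median iteration, covariate-adjusted per-taxon Wald tests, Holm
  step-down FWER control.
* **Batch correction** (`vmec.batch`) — parametric empirical-Bayes
  location/scale adjustment (ComBat-style) with a protected disease design
  and frozen-parameter application to unseen cohorts.
* **Rebalancing & imputation** (`vmec.resample`) — SMOTE-NC for mixed
  numeric/categorical features and chained-equation (MICE-style) covariate
  imputation with frozen per-column models.
* **Ensemble framework** (`vmec.ensemble`) — the core: early integration
  (pooled, raw or batch-corrected) versus late integration (one local model
  per cohort on CLR genus features and/or covariates, probabilities
  averaged, hard calls at 0.5), grid-search tuning under repeated stratified
  CV optimized for F1, held-out evaluation and leave-one-study-out (LOSO)
  validation with covariate-restricted retraining.
* **Metrics** (`vmec.metrics`) — sensitivity/specificity/PPV/NPV with exact
  Clopper-Pearson 95% CIs (undefined metrics flagged, CI [0, 1]), rank-based
  AUROC, micro-pooled LOSO reports.

## Worked example

```python
import pandas as pd
import vmec
from vmec.ensemble import ModelSpec, evaluate_held_out

study = vmec.simulate_multicohort(
    vmec.SimulationConfig(seed=1, sequencing_depth_mean=5000)
)
spec = ModelSpec(
    variant="late_covariates_microbiome", seed=1, cv_repeats=1,
    grids={"bagged_trees": [{"n_estimators": 200, "max_features": "sqrt"}]},
)
fitted, preds, report = evaluate_held_out(study, spec)
print(report.to_markdown())
```

prints

```
| NPV | Sensitivity | PPV | Specificity | AUROC |
|---|---|---|---|---|
| 1.00 [0.69, 1.00] | 1.00 [0.74, 1.00] | 1.00 [0.74, 1.00] | 1.00 [0.69, 1.00] | 1.00 |
```

i.e. on the 22-sample held-out cohort (12 EC / 10 benign) the late ensemble
classifies every sample correctly at the 0.5 threshold under this seed's
strong planted signal; the brackets are exact 95% binomial intervals,
deliberately wide at this test-set size (a perfect sensitivity on 12 cases
is still only bounded below by 0.74).

The numbered scripts under `analysis/` run the full narrative on simulated
data — cohort design (`01`), diversity and PERMANOVA (`02`), differential
abundance (`03`, recovering the planted *Peptoniphilus*-like enrichment),
batch correction (`04`, cohort-clustering R² drops ≈99% while the protected
disease term survives), the six-variant integration benchmark (`05`) and
LOSO validation (`06`) — writing their tables under `results/`.

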