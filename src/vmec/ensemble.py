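"""Early- and late-integration ensemble classification across cohorts.

Two ways to combine case-control 16S cohorts into one classifier:

* **Early integration** pools all training cohorts into a single matrix
  before modelling — either raw (``early_raw``) or after empirical-Bayes
  batch correction (``early_batch_corrected``).
* **Late integration** trains one local model per training cohort on that
  cohort's own feature set (microbiome only, covariates only, covariates +
  pH, or covariates + microbiome) and averages the local probabilities on
  new samples; the hard call is positive when the mean probability is >= 0.5.

Each training unit tunes its learners by grid search under repeated
stratified cross-validation optimized for F1 at the 0.5 threshold, with
imputation and minority oversampling performed strictly inside training
folds.  Leave-one-study-out (LOSO) validation retrains the whole ensemble
once per cohort, restricted to the covariates available in the held-out
study, and reports per-study plus micro-pooled metrics.

Every preprocessing decision (prevalence filter list, CLR pseudocount,
imputation models, batch parameters, tuned configuration) derives from
training data only and is frozen before touching evaluation samples.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .batch import BatchModel, fit_apply_combat
from .features import (
    CATEGORICAL_COVARIATE,
    FeatureMatrix,
    build_feature_matrix,
)
from .metrics import MetricReport, pool_reports
from .resample import ChainedImputer, RebalancePlan, smote_nc
from .simulate import CohortDataset, MultiCohortStudy

logger = logging.getLogger(__name__)

VARIANTS = (
    "early_raw",
    "early_batch_corrected",
    "late_microbiome",
    "late_covariates",
    "late_covariates_ph",
    "late_covariates_microbiome",
)
_BASE_COVARIATES = ("age", "bmi", "ethnicity")

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "bagged_trees": [
        {"n_estimators": 200, "max_features": "sqrt"},
        {"n_estimators": 200, "max_features": 0.3},
    ],
    "boosted_trees": [
        {"n_estimators": 100, "max_depth": 2, "learning_rate": 0.1},
        {"n_estimators": 200, "max_depth": 3, "learning_rate": 0.1},
    ],
    "neural_net": [
        {"hidden_units": 8},
        {"hidden_units": 16},
    ],
}


def _complexity(family: str, params: dict) -> float:
    """Tie-break key: simpler configurations first."""
    if family == "bagged_trees":
        return params.get("n_estimators", 0)
    if family == "boosted_trees":
        return params.get("n_estimators", 0) * params.get("max_depth", 1)
    if family == "neural_net":
        return params.get("hidden_units", 0)
    return 0.0


def make_learner(family: str, params: dict, seed: int) -> Pipeline:
    """Instantiate a base learner behind the uniform fit/predict_proba surface."""
    if family == "bagged_trees":
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    elif family == "boosted_trees":
        est = XGBClassifier(
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
            **params,
        )
    elif family == "neural_net":
        est = MLPClassifier(
            hidden_layer_sizes=(params["hidden_units"],),
            max_iter=800,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown learner family {family!r}")
    return Pipeline([("scale", StandardScaler()), ("model", est)])


@dataclass
class ModelSpec:
    """Training configuration for one integration variant."""

    variant: str = "late_covariates_microbiome"
    grids: dict[str, list[dict]] = field(default_factory=lambda: {
        k: [dict(p) for p in v] for k, v in DEFAULT_GRIDS.items()
    })
    cv_folds: int = 5
    cv_repeats: int = 3
    threshold: float = 0.5
    seed: int = 0
    combine: str = "average_families"  # or "best_family"
    weighting: str = "uniform"  # or "oof_f1"
    prevalence_threshold: float = 0.05
    pseudocount: float = 0.5
    use_smote: bool = True
    smote_k: int = 5
    protect_disease_in_combat: bool = True

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not self.grids or any(len(v) == 0 for v in self.grids.values()):
            raise ValueError("grids must be non-empty")


def variant_covariates(variant: str) -> tuple[str, ...]:
    if variant in ("early_raw", "early_batch_corrected", "late_microbiome"):
        return ()
    if variant == "late_covariates_ph":
        return _BASE_COVARIATES + ("ph",)
    return _BASE_COVARIATES


def variant_uses_taxa(variant: str) -> bool:
    return variant in (
        "early_raw",
        "early_batch_corrected",
        "late_microbiome",
        "late_covariates_microbiome",
    )


# ------------------------------------------------------------------ local model

def _encode(values: pd.DataFrame, kinds: dict[str, str],
            categories: dict[str, list[str]] | None = None):
    """One-hot categorical columns with frozen category lists."""
    blocks, cats = [], {}
    for c in values.columns:
        if kinds.get(c) == CATEGORICAL_COVARIATE:
            levels = (
                categories[c]
                if categories is not None
                else sorted(values[c].astype(str).unique())
            )
            cats[c] = levels
            codes = pd.Categorical(values[c].astype(str), categories=levels)
            dummies = pd.get_dummies(codes, prefix=c).astype(float)
            dummies.index = values.index
            blocks.append(dummies)
        else:
            blocks.append(values[[c]].astype(float))
    return pd.concat(blocks, axis=1), cats


@dataclass
class TunedChoice:
    family: str
    params: dict
    oof_f1: float


class LocalModel:
    """One training unit: frozen preprocessing + tuned base learners.

    Owns the whole per-unit pipeline: genus aggregation, prevalence filter
    (learned here, frozen), CLR, covariate imputation (models frozen),
    in-fold SMOTE-NC during tuning, grid-search selection by mean
    out-of-fold F1 at the spec threshold, and the final refit on all of the
    unit's training data.
    """

    def __init__(self, unit_id: str, spec: ModelSpec, use_taxa: bool,
                 covariates: tuple[str, ...], seed: int):
        self.unit_id = unit_id
        self.spec = spec
        self.use_taxa = use_taxa
        self.covariates = tuple(covariates)
        self.seed = seed
        self.feature_matrix_: FeatureMatrix | None = None
        self.imputer_: ChainedImputer | None = None
        self.categories_: dict[str, list[str]] = {}
        self.encoded_columns_: list[str] = []
        self.choices_: list[TunedChoice] = []
        self.models_: dict[str, Pipeline] = {}
        self.oof_f1_: float = np.nan
        self.precorrected_: pd.DataFrame | None = None

    # -- feature assembly ------------------------------------------------
    def _assemble(self, cohort: CohortDataset, frozen_taxa=None) -> FeatureMatrix:
        covs = cohort.covariates[[c for c in self.covariates
                                  if c in cohort.covariates.columns]]
        fm = build_feature_matrix(
            counts=cohort.counts,
            taxonomy=cohort.taxonomy,
            labels=cohort.labels,
            covariates=covs if len(covs.columns) else None,
            prevalence_threshold=self.spec.prevalence_threshold,
            pseudocount=self.spec.pseudocount,
            frozen_taxa=frozen_taxa,
        )
        if not self.use_taxa:
            fm = fm.subset_columns(fm.covariate_columns())
        return fm

    def _split_blocks(self, fm_values: pd.DataFrame):
        taxa = [c for c in fm_values.columns if c in self._taxa_set]
        covs = [c for c in fm_values.columns if c not in self._taxa_set]
        return fm_values[taxa], fm_values[covs]

    def _complete(self, values: pd.DataFrame, fit: bool) -> pd.DataFrame:
        """Impute covariate block (conditioning on taxa block when present)."""
        taxa_block, cov_block = self._split_blocks(values)
        if cov_block.shape[1] == 0:
            return values
        imputer = ChainedImputer(seed=self.seed) if fit else self.imputer_
        micro = taxa_block if taxa_block.shape[1] else None
        completed = (
            imputer.fit_transform(cov_block, micro)
            if fit
            else imputer.transform(cov_block, micro)
        )
        if fit:
            self.imputer_ = imputer
        return pd.concat([taxa_block, completed], axis=1)[values.columns]

    # -- tuning ----------------------------------------------------------
    def _cv_f1(self, x: pd.DataFrame, y: pd.Series, kinds, family, params) -> float:
        y01 = (y == "EC").astype(int).to_numpy()
        counts = np.bincount(y01, minlength=2)
        n_splits = min(self.spec.cv_folds, counts.min())
        if n_splits < 2:
            raise ValueError(
                f"unit {self.unit_id}: class too small for stratified CV"
            )
        if n_splits < self.spec.cv_folds:
            logger.warning(
                "unit %s: reduced folds %d -> %d to keep both classes per fold",
                self.unit_id, self.spec.cv_folds, n_splits,
            )
        cv = RepeatedStratifiedKFold(
            n_splits=n_splits, n_repeats=self.spec.cv_repeats,
            random_state=self.seed,
        )
        cat_cols = [c for c, k in kinds.items()
                    if k == CATEGORICAL_COVARIATE and c in x.columns]
        f1s = []
        for fold_i, (tr, va) in enumerate(cv.split(x, y01)):
            x_tr = x.iloc[tr].copy()
            y_tr = y.iloc[tr]
            x_va = x.iloc[va].copy()
            # impute inside the fold, frozen for the validation part
            imputer = None
            taxa_tr, cov_tr = self._split_blocks(x_tr)
            taxa_va, cov_va = self._split_blocks(x_va)
            if cov_tr.shape[1]:
                imputer = ChainedImputer(seed=self.seed)
                cov_tr = imputer.fit_transform(
                    cov_tr, taxa_tr if taxa_tr.shape[1] else None
                )
                cov_va = imputer.transform(
                    cov_va, taxa_va if taxa_va.shape[1] else None
                )
                x_tr = pd.concat([taxa_tr, cov_tr], axis=1)[x.columns]
                x_va = pd.concat([taxa_va, cov_va], axis=1)[x.columns]
            if self.spec.use_smote and y_tr.value_counts().min() >= 2 \
                    and y_tr.nunique() == 2:
                plan = RebalancePlan(
                    k_neighbors=self.spec.smote_k,
                    categorical_features=cat_cols,
                    seed=self.seed + fold_i,
                )
                x_tr, y_tr = smote_nc(x_tr, y_tr, plan)
            enc_tr, cats = _encode(x_tr, kinds)
            enc_va, _ = _encode(x_va, kinds, categories=cats)
            learner = make_learner(family, params, self.seed)
            learner.fit(enc_tr.to_numpy(), (y_tr == "EC").astype(int).to_numpy())
            prob = learner.predict_proba(enc_va.to_numpy())[:, 1]
            pred = (prob >= self.spec.threshold).astype(int)
            f1s.append(f1_score(y01[va], pred, zero_division=0))
        return float(np.mean(f1s))

    def fit(self, cohort: CohortDataset) -> "LocalModel":
        fm = self._assemble(cohort)
        self._taxa_set = set(fm.taxon_columns())
        self.feature_matrix_ = fm
        x, y, kinds = fm.values, fm.labels, fm.feature_kinds

        results = {}
        for family, grid in self.spec.grids.items():
            scored = []
            for gi, params in enumerate(grid):
                f1 = self._cv_f1(x, y, kinds, family, params)
                scored.append((f1, -_complexity(family, params), -gi, params))
            # best F1; ties -> simpler model, then earlier grid position
            scored.sort(key=lambda t: (t[0], t[1], t[2]), reverse=True)
            best = scored[0]
            results[family] = TunedChoice(family=family, params=best[3], oof_f1=best[0])

        if self.spec.combine == "best_family":
            top = max(
                results.values(),
                key=lambda c: (c.oof_f1, -_complexity(c.family, c.params)),
            )
            chosen = [top]
        else:
            chosen = list(results.values())
        self.choices_ = chosen
        self.oof_f1_ = float(np.mean([c.oof_f1 for c in chosen]))

        # final refit on the full training unit
        x_full = self._complete(x, fit=True)
        y_full = y
        cat_cols = [c for c, k in kinds.items()
                    if k == CATEGORICAL_COVARIATE and c in x.columns]
        if self.spec.use_smote and y_full.value_counts().min() >= 2 \
                and y_full.nunique() == 2:
            plan = RebalancePlan(
                k_neighbors=self.spec.smote_k,
                categorical_features=cat_cols,
                seed=self.seed,
            )
            x_full, y_full = smote_nc(x_full, y_full, plan)
        enc, cats = _encode(x_full, kinds)
        self.categories_ = cats
        self.encoded_columns_ = list(enc.columns)
        y01 = (y_full == "EC").astype(int).to_numpy()
        for choice in chosen:
            learner = make_learner(choice.family, choice.params, self.seed)
            learner.fit(enc.to_numpy(), y01)
            self.models_[choice.family] = learner
        return self

    # -- prediction -------------------------------------------------------
    def feature_list(self) -> list[str]:
        return list(self.feature_matrix_.values.columns)

    def prepare_features(self, cohort: CohortDataset) -> pd.DataFrame:
        fm = self._assemble(cohort, frozen_taxa=self.feature_matrix_.frozen_taxa)
        missing = [c for c in self.feature_list() if c not in fm.values.columns]
        if missing:
            raise ValueError(
                f"unit {self.unit_id}: features unavailable at prediction "
                f"time: {missing[:5]}"
            )
        values = fm.values[self.feature_list()]
        values = self._complete(values, fit=False)
        enc, _ = _encode(values, self.feature_matrix_.feature_kinds,
                         categories=self.categories_)
        return enc[self.encoded_columns_]

    def predict_proba(self, cohort: CohortDataset,
                      features: pd.DataFrame | None = None) -> np.ndarray:
        enc = self.prepare_features(cohort) if features is None else features
        probs = [m.predict_proba(enc.to_numpy())[:, 1] for m in self.models_.values()]
        return np.mean(probs, axis=0)


# ------------------------------------------------------------------ ensemble

@dataclass
class PredictionSet:
    sample_ids: list[str]
    local_probabilities: pd.DataFrame  # samples x contributing units
    averaged: np.ndarray
    hard_labels: np.ndarray  # 1 = EC call
    y_true: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        out = self.local_probabilities.copy()
        out["averaged"] = self.averaged
        out["call_ec"] = self.hard_labels
        if self.y_true is not None:
            out["truth_ec"] = self.y_true
        return out


@dataclass
class FittedEnsemble:
    variant: str
    spec: ModelSpec
    local_models: dict[str, LocalModel]
    batch_model: BatchModel | None = None
    skipped_cohorts: list[str] = field(default_factory=list)

    def predict(self, cohort: CohortDataset) -> PredictionSet:
        return predict_ensemble(self, cohort)


def _pool_training(study: MultiCohortStudy) -> CohortDataset:
    counts, labels, covs, _ = study.pooled("training")
    return CohortDataset(
        cohort_id="pooled_training",
        counts=counts,
        taxonomy=study.taxonomy,
        labels=labels,
        covariates=covs,
        tree=study.tree,
    )


def _restricted_covariates(variant: str, cohort: CohortDataset,
                           allowed: tuple[str, ...] | None) -> tuple[str, ...]:
    wanted = variant_covariates(variant)
    avail = set(cohort.available_covariates)
    out = tuple(c for c in wanted if c in avail and (allowed is None or c in allowed))
    return out


def fit_ensemble(
    study: MultiCohortStudy,
    spec: ModelSpec,
    allowed_covariates: tuple[str, ...] | None = None,
) -> FittedEnsemble:
    """Fit the chosen integration variant on the study's training cohorts.

    ``allowed_covariates`` restricts covariate features further (used by LOSO
    to honor the held-out study's availability).  The held-out cohort never
    enters any fitting step.
    """
    training = study.training_cohorts()
    if "late" in spec.variant and len(training) < 2:
        raise ValueError("late integration needs >= 2 training cohorts")
    # a local model's covariates must be observable in the held-out cohort
    held_avail = tuple(study.held_out_cohort().available_covariates)
    allowed_covariates = tuple(
        c for c in (allowed_covariates or variant_covariates(spec.variant))
        if c in held_avail
    )
    local_models: dict[str, LocalModel] = {}
    skipped: list[str] = []
    batch_model = None

    if spec.variant in ("early_raw", "early_batch_corrected"):
        pooled = _pool_training(study)
        unit = LocalModel(
            unit_id="pooled",
            spec=spec,
            use_taxa=True,
            covariates=(),
            seed=spec.seed,
        )
        if spec.variant == "early_batch_corrected":
            # build pooled CLR features, correct them, then let the unit
            # train on the corrected matrix via a patched assembly
            fm = unit._assemble(pooled)
            _, _, _, batch_series = study.pooled("training")
            protect = pooled.labels if spec.protect_disease_in_combat else None
            corrected, batch_model = fit_apply_combat(
                fm.values, batch_series, protect=protect
            )
            unit.fit(_corrected_cohort(pooled, corrected, fm, unit))
        else:
            unit.fit(pooled)
        local_models["pooled"] = unit
    else:
        for cohort in training:
            covs = _restricted_covariates(spec.variant, cohort, allowed_covariates)
            use_taxa = variant_uses_taxa(spec.variant)
            if not use_taxa and len(covs) == 0:
                skipped.append(cohort.cohort_id)
                logger.info(
                    "variant %s: cohort %s has no usable covariates; skipped",
                    spec.variant, cohort.cohort_id,
                )
                continue
            # cohort-id-derived seed: dropping one cohort leaves the other
            # local models bit-identical
            unit_seed = (spec.seed + zlib.crc32(cohort.cohort_id.encode())) % (2**31)
            unit = LocalModel(
                unit_id=cohort.cohort_id,
                spec=spec,
                use_taxa=use_taxa,
                covariates=covs,
                seed=unit_seed,
            )
            unit.fit(cohort)
            local_models[cohort.cohort_id] = unit
        if not local_models:
            raise ValueError("no training cohort could contribute a local model")

    return FittedEnsemble(
        variant=spec.variant,
        spec=spec,
        local_models=local_models,
        batch_model=batch_model,
        skipped_cohorts=skipped,
    )


def _corrected_cohort(pooled, corrected, fm, unit) -> CohortDataset:
    """Wrap batch-corrected CLR features so LocalModel can consume them.

    The unit's assembly is monkey-patched to return the corrected matrix:
    correction happens once, up front, on training data only.
    """
    frozen = fm.frozen_taxa

    def assemble(cohort, frozen_taxa=None):
        if cohort.cohort_id == pooled.cohort_id:
            return FeatureMatrix(
                values=corrected,
                feature_kinds=dict(fm.feature_kinds),
                labels=fm.labels,
                frozen_taxa=frozen,
            )
        base = build_feature_matrix(
            counts=cohort.counts,
            taxonomy=cohort.taxonomy,
            labels=cohort.labels,
            prevalence_threshold=unit.spec.prevalence_threshold,
            pseudocount=unit.spec.pseudocount,
            frozen_taxa=frozen,
        )
        adjusted = unit._ensemble_batch_model.transform_new_batch(base.values)
        return FeatureMatrix(
            values=adjusted,
            feature_kinds=dict(fm.feature_kinds),
            labels=base.labels,
            frozen_taxa=frozen,
        )

    unit._assemble = assemble  # type: ignore[method-assign]
    return pooled


def predict_ensemble(fitted: FittedEnsemble, cohort: CohortDataset) -> PredictionSet:
    """Average contributing local-model probabilities and threshold at 0.5."""
    if not fitted.local_models:
        raise ValueError("no applicable local model")
    probs = {}
    weights = {}
    for uid, unit in fitted.local_models.items():
        if fitted.batch_model is not None:
            unit._ensemble_batch_model = fitted.batch_model
        probs[uid] = unit.predict_proba(cohort)
        weights[uid] = unit.oof_f1_ if fitted.spec.weighting == "oof_f1" else 1.0
    frame = pd.DataFrame(probs, index=cohort.counts.index)
    w = np.array([weights[c] for c in frame.columns], dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    averaged = (frame.to_numpy() * w).sum(axis=1) / w.sum()
    hard = (averaged >= fitted.spec.threshold).astype(int)
    y_true = (cohort.labels == "EC").astype(int).to_numpy()
    return PredictionSet(
        sample_ids=list(cohort.counts.index),
        local_probabilities=frame,
        averaged=averaged,
        hard_labels=hard,
        y_true=y_true,
    )


def evaluate_held_out(study: MultiCohortStudy, spec: ModelSpec) -> tuple[
    FittedEnsemble, PredictionSet, MetricReport
]:
    """Fit on training cohorts, evaluate once on the designated held-out."""
    fitted = fit_ensemble(study, spec)
    preds = predict_ensemble(fitted, study.held_out_cohort())
    report = MetricReport.from_scores(
        preds.y_true, preds.averaged, threshold=spec.threshold,
        provenance={"variant": spec.variant, "held_out": study.held_out},
    )
    return fitted, preds, report


def loso_validate(study: MultiCohortStudy, spec: ModelSpec) -> dict:
    """Leave-one-study-out validation with covariate-restricted retraining."""
    if len(study.cohorts) < 3:
        raise ValueError("LOSO needs >= 3 cohorts")
    per_study: dict[str, MetricReport] = {}
    all_scores: list[np.ndarray] = []
    all_truth: list[np.ndarray] = []
    for cid in study.cohort_ids:
        fold = study.with_held_out(cid)
        held = fold.held_out_cohort()
        allowed = tuple(
            c for c in variant_covariates(spec.variant)
            if c in held.available_covariates
        )
        fitted = fit_ensemble(fold, spec, allowed_covariates=allowed or None)
        preds = predict_ensemble(fitted, held)
        report = MetricReport.from_scores(
            preds.y_true, preds.averaged, threshold=spec.threshold,
            provenance={"variant": spec.variant, "held_out": cid,
                        "covariates_used": list(allowed)},
        )
        per_study[cid] = report
        all_scores.append(preds.averaged)
        all_truth.append(preds.y_true)
    scores = np.concatenate(all_scores)
    truth = np.concatenate(all_truth)
    pooled = pool_reports(list(per_study.values()), truth, scores)
    return {"per_study": per_study, "pooled": pooled,
            "scores": scores, "truth": truth}
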