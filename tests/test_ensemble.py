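import numpy as np
import pandas as pd
import pytest

import vmec
from vmec.ensemble import (
    FittedEnsemble,
    LocalModel,
    ModelSpec,
    fit_ensemble,
    loso_validate,
    predict_ensemble,
)
from vmec.simulate import CohortDataset


def _separable_cohort(n=40, seed=0):
    """Labels are a deterministic threshold of one taxon's abundance."""
    rng = np.random.default_rng(seed)
    labels = np.array(["EC"] * (n // 2) + ["benign"] * (n // 2))
    counts = rng.integers(5, 50, size=(n, 6))
    counts[:, 0] = np.where(labels == "EC", 2000, 5)
    idx = [f"s{i}" for i in range(n)]
    taxonomy = pd.Series(
        [f"d__B;g__G{i};s__x" for i in range(6)],
        index=[f"t{i}" for i in range(6)],
    )
    return CohortDataset(
        cohort_id="toy",
        counts=pd.DataFrame(counts, index=idx, columns=taxonomy.index),
        taxonomy=taxonomy,
        labels=pd.Series(labels, index=idx, name="diagnosis"),
        covariates=pd.DataFrame(index=idx),
    )


class _StubUnit:
    def __init__(self, probs, oof=1.0):
        self._p = np.asarray(probs, dtype=float)
        self.oof_f1_ = oof

    def predict_proba(self, cohort, features=None):
        return self._p


def _stub_cohort(n):
    idx = [f"s{i}" for i in range(n)]
    taxonomy = pd.Series(["d__B;g__G;s__x"], index=["t0"])
    return CohortDataset(
        cohort_id="x",
        counts=pd.DataFrame({"t0": [1] * n}, index=idx),
        taxonomy=taxonomy,
        labels=pd.Series(["EC"] * n, index=idx),
        covariates=pd.DataFrame(index=idx),
    )


class TestLocalModelTuning:
    def test_separable_cohort_perfect_oof_f1(self, tiny_spec):
        spec = tiny_spec(variant="late_microbiome")
        unit = LocalModel("toy", spec, use_taxa=True, covariates=(), seed=0)
        unit.fit(_separable_cohort())
        assert unit.choices_[0].oof_f1 == 1.0

    def test_randomized_labels_fall_in_null_band(self, tiny_spec):
        """Shuffled labels give chance-level out-of-fold F1."""
        spec = tiny_spec(variant="late_microbiome")
        f1s = []
        for seed in range(5):
            cohort = _separable_cohort(seed=seed)
            rng = np.random.default_rng(seed)
            shuffled = cohort.labels.sample(frac=1.0, random_state=seed)
            shuffled.index = cohort.labels.index
            cohort = CohortDataset(
                cohort_id="null",
                counts=cohort.counts,
                taxonomy=cohort.taxonomy,
                labels=shuffled,
                covariates=cohort.covariates,
            )
            unit = LocalModel("null", spec, use_taxa=True, covariates=(), seed=seed)
            unit.fit(cohort)
            f1s.append(unit.choices_[0].oof_f1)
        assert 0.2 <= np.mean(f1s) <= 0.75

    def test_determinism_of_selection_and_predictions(self, tiny_spec):
        spec = tiny_spec(
            variant="late_microbiome",
            grids={"bagged_trees": [
                {"n_estimators": 50, "max_features": "sqrt"},
                {"n_estimators": 100, "max_features": 0.5},
            ]},
        )
        cohort = _separable_cohort()
        a = LocalModel("toy", spec, use_taxa=True, covariates=(), seed=1).fit(cohort)
        b = LocalModel("toy", spec, use_taxa=True, covariates=(), seed=1).fit(cohort)
        assert a.choices_[0].params == b.choices_[0].params
        assert np.allclose(a.predict_proba(cohort), b.predict_proba(cohort))

    def test_tie_break_prefers_simpler_model(self, tiny_spec):
        # both grid points reach F1 = 1 on a separable cohort; the smaller
        # forest must win
        spec = tiny_spec(
            variant="late_microbiome",
            grids={"bagged_trees": [
                {"n_estimators": 120, "max_features": "sqrt"},
                {"n_estimators": 40, "max_features": "sqrt"},
            ]},
        )
        unit = LocalModel("toy", spec, use_taxa=True, covariates=(), seed=0)
        unit.fit(_separable_cohort())
        assert unit.choices_[0].params["n_estimators"] == 40


class TestEnsembleStructure:
    def test_late_variant_one_model_per_training_cohort(self, small_study, tiny_spec):
        fitted = fit_ensemble(
            small_study, tiny_spec(variant="late_covariates_microbiome")
        )
        assert sorted(fitted.local_models) == ["b", "c"]

    def test_cohort_without_covariates_skipped_in_covariates_only(
        self, default_study, tiny_spec
    ):
        fitted = fit_ensemble(default_study, tiny_spec(variant="late_covariates"))
        assert "gressel" in fitted.skipped_cohorts
        assert "gressel" not in fitted.local_models

    def test_removing_cohort_leaves_other_local_models_unchanged(self, tiny_spec):
        from tests.conftest import small_config

        cfg = small_config(
            seed=13,
            cohort_ids=("a", "b", "c", "d"),
            cohort_sizes=(24, 40, 24, 20),
            ec_counts=(12, 18, 12, 10),
            missingness_plan={"a": (), "b": (), "c": (), "d": ()},
        )
        study = vmec.simulate_multicohort(cfg)
        spec = tiny_spec(variant="late_microbiome")
        full = fit_ensemble(study, spec)
        reduced_study = vmec.MultiCohortStudy(
            cohorts=[c for c in study.cohorts if c.cohort_id != "d"],
            held_out=study.held_out,
            taxonomy=study.taxonomy,
            tree=study.tree,
        )
        reduced = fit_ensemble(reduced_study, spec)
        held = study.held_out_cohort()
        assert np.allclose(
            full.local_models["b"].predict_proba(held),
            reduced.local_models["b"].predict_proba(held),
        )

    def test_too_few_training_cohorts(self, small_study, tiny_spec):
        solo = vmec.MultiCohortStudy(
            cohorts=[small_study.get("a"), small_study.get("b")],
            held_out="a",
            taxonomy=small_study.taxonomy,
            tree=small_study.tree,
        )
        with pytest.raises(ValueError, match=">= 2 training cohorts"):
            fit_ensemble(solo, tiny_spec(variant="late_microbiome"))


class TestPredictionAveraging:
    def test_stated_averaging_rule(self, tiny_spec):
        cohort = _stub_cohort(1)
        fitted = FittedEnsemble(
            variant="late_microbiome",
            spec=tiny_spec(variant="late_microbiome"),
            local_models={
                "u1": _StubUnit([0.2]), "u2": _StubUnit([0.4]),
                "u3": _StubUnit([0.9]),
            },
        )
        preds = predict_ensemble(fitted, cohort)
        assert preds.averaged[0] == pytest.approx(0.5)
        assert preds.hard_labels[0] == 1  # >= 0.5 classifies positive

    def test_cohort_order_permutation_invariant(self, tiny_spec):
        cohort = _stub_cohort(3)
        units = {"a": _StubUnit([0.1, 0.6, 0.9]), "b": _StubUnit([0.3, 0.2, 0.8])}
        spec = tiny_spec(variant="late_microbiome")
        f1 = FittedEnsemble("late_microbiome", spec, dict(units))
        f2 = FittedEnsemble(
            "late_microbiome", spec, dict(reversed(list(units.items())))
        )
        assert np.allclose(
            predict_ensemble(f1, cohort).averaged,
            predict_ensemble(f2, cohort).averaged,
        )

    def test_single_model_reduces_to_itself(self, tiny_spec):
        cohort = _stub_cohort(2)
        fitted = FittedEnsemble(
            "late_microbiome", tiny_spec(variant="late_microbiome"),
            {"only": _StubUnit([0.7, 0.1])},
        )
        preds = predict_ensemble(fitted, cohort)
        assert np.allclose(preds.averaged, [0.7, 0.1])

    def test_no_models_raises(self, tiny_spec):
        with pytest.raises(ValueError, match="no applicable"):
            predict_ensemble(
                FittedEnsemble(
                    "late_microbiome", tiny_spec(variant="late_microbiome"), {}
                ),
                _stub_cohort(1),
            )


class TestLoso:
    def test_structure_and_reports(self, small_study, tiny_spec):
        res = loso_validate(small_study, tiny_spec(variant="late_microbiome"))
        assert sorted(res["per_study"]) == ["a", "b", "c"]
        assert res["pooled"].counts.n == sum(
            len(c.counts) for c in small_study.cohorts
        )
        for rep in res["per_study"].values():
            assert rep.counts.n > 0

    def test_needs_three_cohorts(self, small_study, tiny_spec):
        two = vmec.MultiCohortStudy(
            cohorts=small_study.cohorts[:2],
            held_out="a",
            taxonomy=small_study.taxonomy,
            tree=small_study.tree,
        )
        with pytest.raises(ValueError, match=">= 3"):
            loso_validate(two, tiny_spec(variant="late_microbiome"))
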