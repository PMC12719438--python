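import numpy as np
import pandas as pd
import pytest
import skbio
from io import StringIO

import vmec
from vmec.simulate import (
    SimulationConfig,
    null_config,
    read_study,
    simulate_multicohort,
    simulate_tree,
    write_study,
)
from tests.conftest import small_config


class TestDefaultDesign:
    def test_table_shaped_totals(self, default_study):
        counts, labels, covs, batch = default_study.pooled("all")
        assert len(labels) == 265
        assert (labels == "EC").sum() == 135
        assert (labels == "benign").sum() == 130
        sizes = {c.cohort_id: len(c.counts) for c in default_study.cohorts}
        assert sizes == {
            "antonio": 22, "walsh": 149, "tsementzi": 36, "chao": 27, "gressel": 31,
        }
        ec = {c.cohort_id: int((c.labels == "EC").sum()) for c in default_study.cohorts}
        assert ec == {"antonio": 12, "walsh": 69, "tsementzi": 8, "chao": 23,
                      "gressel": 23}

    def test_covariate_availability_matches_plan(self, default_study):
        avail = {c.cohort_id: set(c.available_covariates)
                 for c in default_study.cohorts}
        assert avail["chao"] == {"age"}
        assert avail["gressel"] == set()
        for cid in ("antonio", "walsh", "tsementzi"):
            assert avail[cid] == {"age", "bmi", "ethnicity", "ph"}

    def test_counts_valid(self, default_study):
        for c in default_study.cohorts:
            arr = c.counts.to_numpy()
            assert (arr >= 0).all()
            assert (arr.sum(axis=1) > 0).all()
            assert set(c.labels.unique()) == {"EC", "benign"}

    def test_ec_samples_older_on_average(self, default_study):
        c = default_study.get("walsh")
        ages = c.covariates["age"]
        assert ages[c.labels == "EC"].mean() > ages[c.labels == "benign"].mean()


class TestDeterminismAndSeeding:
    def test_same_seed_bit_identical(self):
        a = simulate_multicohort(small_config(seed=9))
        b = simulate_multicohort(small_config(seed=9))
        for ca, cb in zip(a.cohorts, b.cohorts):
            pd.testing.assert_frame_equal(ca.counts, cb.counts)
            pd.testing.assert_frame_equal(ca.covariates, cb.covariates)
            assert (ca.labels == cb.labels).all()

    def test_appending_cohort_preserves_earlier_ones(self):
        base = small_config(seed=5)
        extended = small_config(
            seed=5,
            cohort_ids=("a", "b", "c", "d"),
            cohort_sizes=(24, 40, 24, 20),
            ec_counts=(12, 18, 12, 10),
            missingness_plan={
                "a": ("age", "bmi", "ethnicity", "ph"),
                "b": ("age", "bmi", "ethnicity", "ph"),
                "c": ("age",),
                "d": (),
            },
        )
        sa = simulate_multicohort(base)
        sb = simulate_multicohort(extended)
        for cid in ("a", "b", "c"):
            pd.testing.assert_frame_equal(sa.get(cid).counts, sb.get(cid).counts)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="align"):
            simulate_multicohort(
                SimulationConfig(
                    cohort_ids=("a",), cohort_sizes=(2, 3), ec_counts=(1,)
                )
            )
        with pytest.raises(ValueError, match="single-class"):
            simulate_multicohort(
                SimulationConfig(
                    cohort_ids=("a", "tiny"),
                    cohort_sizes=(24, 1),
                    ec_counts=(12, 1),
                    missingness_plan={"a": (), "tiny": ()},
                    held_out="a",
                )
            )


class TestSignalStructure:
    def test_higher_shannon_in_ec_across_seeds(self):
        """diversity_shift > 0 flattens EC compositions."""
        diffs = []
        for seed in range(20):
            study = simulate_multicohort(
                small_config(seed=seed, diversity_shift=0.3)
            )
            counts, labels, *_ = study.pooled("all")
            sh = vmec.shannon_rows(vmec.relative_abundance(counts))
            diffs.append(sh[labels == "EC"].mean() - sh[labels == "benign"].mean())
        assert np.mean(diffs) > 0

    def test_batch_signal_detectable_by_permanova(self):
        hits = 0
        for seed in range(10):
            study = simulate_multicohort(small_config(seed=seed))
            counts, _, _, batch = study.pooled("all")
            d = vmec.beta_distance(vmec.relative_abundance(counts), "bray_curtis")
            res = vmec.permanova_marginal(
                d, pd.DataFrame({"cohort": batch}), n_perm=99, seed=seed
            )
            hits += int(res.terms["cohort"].p_value <= 0.05)
        assert hits >= 9

    def test_null_config_kills_label_signal(self):
        """No enrichment/diversity/covariate coupling: label p-values null."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            study = simulate_multicohort(
                null_config(seed=seed, **{
                    k: v for k, v in small_config().__dict__.items()
                    if k in ("cohort_ids", "cohort_sizes", "ec_counts",
                             "missingness_plan", "n_taxa",
                             "sequencing_depth_mean", "held_out")
                })
            )
            c = study.get("b")  # within one batch: labels pure noise
            d = vmec.beta_distance(vmec.relative_abundance(c.counts), "bray_curtis")
            res = vmec.permanova_marginal(
                d, pd.DataFrame({"dx": c.labels}), n_perm=99, seed=seed
            )
            hits += int(res.terms["dx"].p_value <= 0.05)
        # binomial(20, 0.05) band: 0..4 rejections
        assert hits <= 4

    def test_ph_tracks_lactobacillus(self, default_study):
        c = default_study.get("walsh")
        ra = vmec.relative_abundance(c.counts)
        lacto = ra[[t for t in ra.columns
                    if "Lactobacillus" in c.taxonomy[t]]].sum(axis=1)
        ph = c.covariates["ph"]
        ok = ph.notna()
        low = lacto[ok & (ph == "<=4.5")].mean()
        high = lacto[ok & (ph == ">4.5")].mean()
        assert low > high


class TestTree:
    def test_two_taxa_cherry(self):
        t = skbio.TreeNode.read(StringIO(simulate_tree(2, seed=0)))
        assert {x.name for x in t.tips()} == {"t000", "t001"}

    def test_structure_and_roundtrip(self):
        nwk = simulate_tree(8, seed=1)
        t = skbio.TreeNode.read(StringIO(nwk))
        assert len(list(t.tips())) == 8
        edges = [n for n in t.traverse(include_self=False)]
        assert len(edges) == 2 * 8 - 2
        assert all((n.length or 0) > 0 for n in edges)
        rewritten = str(t)
        t2 = skbio.TreeNode.read(StringIO(rewritten))
        assert {x.name for x in t2.tips()} == {x.name for x in t.tips()}

    def test_seeds_vary_topology(self):
        trees = {simulate_tree(8, seed=s) for s in range(20)}
        assert len(trees) > 1

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            simulate_tree(1)


class TestIO:
    def test_write_read_roundtrip(self, tmp_path, small_study):
        write_study(small_study, tmp_path)
        assert (tmp_path / "manifest.json").exists()
        back = read_study(tmp_path)
        assert back.held_out == small_study.held_out
        for cid in small_study.cohort_ids:
            pd.testing.assert_frame_equal(
                back.get(cid).counts, small_study.get(cid).counts
            )
            assert (back.get(cid).labels == small_study.get(cid).labels).all()
            # NA pattern survives the round trip
            assert (
                back.get(cid).covariates.isna().sum().tolist()
                == small_study.get(cid).covariates.isna().sum().tolist()
            )
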