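import itertools
import math

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import jensenshannon

import vmec
from vmec.ecology import (
    DistanceMatrix,
    beta_distance,
    gower_center,
    permanova_marginal,
    shannon_index,
    shannon_rows,
)


class TestShannon:
    def test_values(self):
        assert shannon_index([1.0]) == 0.0
        assert shannon_index([0.25] * 4) == pytest.approx(math.log(4))
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_zeros_contribute_nothing(self):
        assert shannon_index([0.5, 0.5, 0.0]) == shannon_index([0.5, 0.5])

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            shannon_index([-0.1, 1.1])

    def test_rowwise_matches_scalar(self):
        df = pd.DataFrame([[0.2, 0.8], [0.5, 0.5]])
        rows = shannon_rows(df)
        assert rows.iloc[0] == pytest.approx(shannon_index([0.2, 0.8]))
        assert rows.iloc[1] == pytest.approx(math.log(2))


def _df(rows, cols=None):
    cols = cols or [f"t{i}" for i in range(len(rows[0]))]
    return pd.DataFrame(rows, columns=cols, index=[f"s{i}" for i in range(len(rows))])


FOUR_LEAF_TREE = "((A:1.0,B:2.0):1.0,(C:3.0,D:1.0):2.0);"
# independent edge table for the tree above: (length, leaves below the edge)
FOUR_LEAF_EDGES = [
    (1.0, {"A"}),
    (2.0, {"B"}),
    (1.0, {"A", "B"}),
    (3.0, {"C"}),
    (1.0, {"D"}),
    (2.0, {"C", "D"}),
]


def _weighted_unifrac_oracle(p, q, taxa):
    num = den = 0.0
    for b, leaves in FOUR_LEAF_EDGES:
        a_e = sum(p[taxa.index(t)] for t in leaves)
        b_e = sum(q[taxa.index(t)] for t in leaves)
        num += b * abs(a_e - b_e)
        den += b * (a_e + b_e)
    return num / den


class TestBetaDistances:
    @pytest.mark.parametrize(
        "metric", ["bray_curtis", "jaccard", "jensen_shannon"]
    )
    def test_identical_samples_distance_zero(self, metric):
        d = beta_distance(_df([[0.2, 0.8], [0.2, 0.8]]), metric)
        assert d.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support(self):
        df = _df([[1, 0], [0, 3]])
        assert beta_distance(df, "bray_curtis").d[0, 1] == 1.0
        assert beta_distance(df, "jaccard").d[0, 1] == 1.0

    def test_bray_curtis_counts_example(self):
        # (2,2) vs (1,3): sum|x-y| = 2, sum(x+y) = 8
        d = beta_distance(_df([[2, 2], [1, 3]]), "bray_curtis")
        assert d.d[0, 1] == pytest.approx(0.25)

    def test_jensen_shannon_matches_scipy(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(6), size=4)
        ours = beta_distance(_df(p.tolist()), "jensen_shannon", jsd_sqrt=True)
        for i, j in itertools.combinations(range(4), 2):
            assert ours.d[i, j] == pytest.approx(jensenshannon(p[i], p[j]), abs=1e-10)

    def test_jsd_sqrt_flag(self):
        df = _df([[0.9, 0.1], [0.1, 0.9]])
        raw = beta_distance(df, "jensen_shannon", jsd_sqrt=False).d[0, 1]
        root = beta_distance(df, "jensen_shannon", jsd_sqrt=True).d[0, 1]
        assert root == pytest.approx(math.sqrt(raw))

    def test_bounded_metrics_stay_below_one(self, small_study):
        counts, *_ = small_study.pooled("all")
        ra = vmec.relative_abundance(counts.iloc[:15])
        for metric in ("bray_curtis", "jaccard", "jensen_shannon"):
            d = beta_distance(ra, metric)
            assert d.d.max() <= 1.0 + 1e-12

    def test_weighted_unifrac_edge_by_edge(self):
        taxa = ["A", "B", "C", "D"]
        samples = [
            [0.5, 0.5, 0.0, 0.0],
            [0.0, 0.0, 0.5, 0.5],
            [0.4, 0.1, 0.25, 0.25],
        ]
        got = beta_distance(
            pd.DataFrame(samples, columns=taxa), "unifrac_weighted",
            tree=FOUR_LEAF_TREE,
        )
        for i, j in itertools.combinations(range(3), 2):
            want = _weighted_unifrac_oracle(samples[i], samples[j], taxa)
            assert got.d[i, j] == pytest.approx(want, abs=1e-12)

    def test_unweighted_unifrac_unshared_over_total(self):
        taxa = ["A", "B", "C", "D"]
        df = pd.DataFrame([[1, 1, 0, 0], [1, 0, 1, 0]], columns=taxa)
        got = beta_distance(df, "unifrac_unweighted", tree=FOUR_LEAF_TREE)
        # present edges: x covers {A,B,AB}; y covers {A,C,AB,CD}
        unshared = 2.0 + 3.0 + 2.0  # B, C, CD edges
        total = 1.0 + 2.0 + 1.0 + 3.0 + 2.0  # A, B, AB, C, CD
        assert got.d[0, 1] == pytest.approx(unshared / total)

    def test_star_tree_reduces_to_half_manhattan(self):
        taxa = [f"L{i}" for i in range(4)]
        star = "(L0:1.0,L1:1.0,L2:1.0,L3:1.0);"
        p = np.array([0.4, 0.3, 0.2, 0.1])
        q = np.array([0.1, 0.2, 0.3, 0.4])
        d = beta_distance(pd.DataFrame([p, q], columns=taxa),
                          "unifrac_weighted", tree=star)
        assert d.d[0, 1] == pytest.approx(np.abs(p - q).sum() / 2.0)

    def test_errors(self):
        df = _df([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="unknown metric"):
            beta_distance(df, "euclidean")
        with pytest.raises(ValueError, match="tree"):
            beta_distance(df, "unifrac_weighted")
        with pytest.raises(ValueError, match="missing from tree"):
            beta_distance(df, "unifrac_weighted", tree="(A:1,B:1);")


class TestDistanceMatrixInvariants:
    def test_rejects_asymmetry_and_negative(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]), "bray_curtis")
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]]), "bray_curtis")
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[1, 0], [0, 1]]), "bray_curtis")


def _brute_force_one_factor(d, groups):
    """Classic PERMANOVA from within-group squared distances."""
    n = len(groups)
    ss_total = sum(
        d[i, j] ** 2 for i, j in itertools.combinations(range(n), 2)
    ) / n
    ss_within = 0.0
    for g in set(groups):
        idx = [i for i in range(n) if groups[i] == g]
        ss_within += sum(
            d[i, j] ** 2 for i, j in itertools.combinations(idx, 2)
        ) / len(idx)
    a = len(set(groups))
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return ss_total, ss_between, f


class TestPermanova:
    def _random_distance(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((n, 5))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        return DistanceMatrix([f"s{i}" for i in range(n)], d, "bray_curtis")

    def test_single_term_equals_classic_decomposition(self):
        dm = self._random_distance(12, 0)
        groups = ["x"] * 6 + ["y"] * 6
        res = permanova_marginal(
            dm, pd.DataFrame({"g": groups}, index=dm.ids), n_perm=99, seed=1
        )
        ss_t, ss_b, f = _brute_force_one_factor(dm.d, groups)
        term = res.terms["g"]
        assert res.total_ss == pytest.approx(ss_t)
        assert term.ss == pytest.approx(ss_b)
        assert term.pseudo_f == pytest.approx(f)
        # R2 terms plus residual sum to 1 in the single-term case
        assert term.r2 + res.residual_ss / res.total_ss == pytest.approx(1.0)

    def test_matches_skbio_one_factor(self):
        dm = self._random_distance(14, 5)
        groups = ["x"] * 7 + ["y"] * 7
        res = permanova_marginal(
            dm, pd.DataFrame({"g": groups}, index=dm.ids), n_perm=99, seed=1
        )
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.d, ids=dm.ids),
            grouping=groups,
            permutations=0,
        )
        assert res.terms["g"].pseudo_f == pytest.approx(sk["test statistic"])

    def test_exhaustive_enumeration_n4(self):
        """Exhaustive p equals an independent enumeration over all 4! relabelings."""
        dm = self._random_distance(4, 2)
        groups = ["x", "x", "y", "y"]
        res = permanova_marginal(
            dm, pd.DataFrame({"g": groups}, index=dm.ids), exhaustive=True
        )
        _, _, f_obs = _brute_force_one_factor(dm.d, groups)
        exceed = 0
        perms = list(itertools.permutations(range(4)))
        for perm in perms:
            relabeled = [groups[perm[i]] for i in range(4)]
            _, _, f = _brute_force_one_factor(dm.d, relabeled)
            if f >= f_obs - 1e-12:
                exceed += 1
        assert res.terms["g"].p_value == pytest.approx(exceed / len(perms))
        assert res.n_permutations == 24

    def test_marginal_terms_with_covariate(self):
        """Marginal SS of each term = SS(full) - SS(without it)."""
        rng = np.random.default_rng(8)
        n = 20
        age = rng.normal(size=n)
        grp = np.where(rng.random(n) < 0.5, "x", "y")
        x = rng.random((n, 4)) + 0.3 * age[:, None]
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(n)], d, "bray_curtis")
        design = pd.DataFrame({"g": grp, "age": age}, index=dm.ids)
        res = permanova_marginal(dm, design, n_perm=99, seed=0)
        g = gower_center(dm.d)

        def ss_model(cols):
            xm = np.column_stack([np.ones(n)] + cols)
            h = xm @ np.linalg.pinv(xm)
            return float(np.sum(h * g))

        ind = (grp == "y").astype(float)
        full = ss_model([ind, age])
        assert res.terms["age"].ss == pytest.approx(full - ss_model([ind]))
        assert res.terms["g"].ss == pytest.approx(full - ss_model([age]))
        for t in res.terms.values():
            assert 0.0 <= t.r2 <= 1.0
            assert 0.0 < t.p_value <= 1.0

    def test_complete_case_dropping(self):
        dm = self._random_distance(10, 3)
        design = pd.DataFrame(
            {"g": ["x"] * 5 + ["y"] * 5, "age": [1.0] * 8 + [np.nan] * 2},
            index=dm.ids,
        )
        design["age"] += np.arange(10)  # keep non-constant
        res = permanova_marginal(dm, design, n_perm=99, seed=0)
        assert len(res.dropped_samples) == 2

    def test_constant_term_raises(self):
        dm = self._random_distance(6, 4)
        with pytest.raises(ValueError, match="constant"):
            permanova_marginal(
                dm, pd.DataFrame({"g": ["x"] * 6}, index=dm.ids), n_perm=99
            )
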