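"""Community ecology summaries: alpha diversity, beta diversity, PERMANOVA.

Implements the metric suite directly from the definitions (Shannon entropy,
Bray-Curtis, Jaccard, Jensen-Shannon, unweighted/weighted UniFrac) and a
marginal-terms PERMANOVA on Gower-centered distance matrices with free
permutation of observations.  Marginal testing assesses each design term
given all others — there is no sequential decomposition and no
multiple-testing correction across terms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from skbio import TreeNode

BOUNDED_METRICS = {"bray_curtis", "jaccard", "jensen_shannon", "unifrac_unweighted"}
KNOWN_METRICS = BOUNDED_METRICS | {"unifrac_weighted"}


# ---------------------------------------------------------------- alpha

def shannon_index(proportions) -> float:
    """Shannon entropy H = -sum p ln p (natural log, 0 ln 0 := 0)."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def shannon_rows(proportions: pd.DataFrame) -> pd.Series:
    """Per-sample Shannon index of a samples x taxa proportion table."""
    arr = proportions.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("proportions must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(arr > 0, arr * np.log(arr), 0.0)
    return pd.Series(-terms.sum(axis=1), index=proportions.index, name="shannon")


# ---------------------------------------------------------------- beta

@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ValueError("diagonal must be zero")
        self.d = np.clip(d, 0.0, None)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


def _entropy_rows(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(p), 0.0)
    return -t.sum(axis=-1)


def _pairwise(x: np.ndarray, fn) -> np.ndarray:
    n = x.shape[0]
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = fn(x[i], x[j])
    return d


def _bray_curtis(a, b):
    denom = (a + b).sum()
    return 0.0 if denom == 0 else np.abs(a - b).sum() / denom


def _jaccard(a, b):
    pa, pb = a > 0, b > 0
    union = (pa | pb).sum()
    return 0.0 if union == 0 else 1.0 - (pa & pb).sum() / union


def _jensen_shannon(a, b, sqrt):
    sa, sb = a.sum(), b.sum()
    p = a / sa if sa > 0 else a
    q = b / sb if sb > 0 else b
    m = 0.5 * (p + q)
    jsd = _entropy_rows(m) - 0.5 * (_entropy_rows(p) + _entropy_rows(q))
    jsd = max(float(jsd), 0.0)
    return math.sqrt(jsd) if sqrt else jsd


class _TreeEdges:
    """Branch lengths and descendant-leaf indicators for every non-root edge."""

    def __init__(self, tree: TreeNode, taxa: list[str]):
        tips = {t.name for t in tree.tips()}
        missing = [t for t in taxa if t not in tips]
        if missing:
            raise ValueError(f"taxa missing from tree: {missing[:5]}")
        index = {t: i for i, t in enumerate(taxa)}
        self.lengths: list[float] = []
        self.indicators: list[np.ndarray] = []
        for node in tree.traverse(include_self=False):
            length = node.length or 0.0
            ind = np.zeros(len(taxa))
            for tip in node.tips(include_self=True):
                if tip.name in index:
                    ind[index[tip.name]] = 1.0
            self.lengths.append(length)
            self.indicators.append(ind)
        self.b = np.asarray(self.lengths)
        self.m = np.asarray(self.indicators)  # edges x taxa


def _as_tree(tree) -> TreeNode:
    if isinstance(tree, TreeNode):
        return tree
    return TreeNode.read(StringIO(str(tree)))


def beta_distance(
    abundances: pd.DataFrame,
    metric: str,
    tree=None,
    jsd_sqrt: bool = True,
) -> DistanceMatrix:
    """Pairwise beta-diversity matrix for one of the supported metrics.

    Bray-Curtis, Jensen-Shannon and weighted UniFrac operate on the rows as
    (relative) abundances; Jaccard and unweighted UniFrac binarize to
    presence/absence internally.  UniFrac metrics require a tree covering
    every taxon column; each sample is renormalized to proportions before
    abundance-weighted branch flows are computed.
    """
    if metric not in KNOWN_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(KNOWN_METRICS)}")
    x = abundances.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    ids = list(abundances.index)

    if metric == "bray_curtis":
        d = _pairwise(x, _bray_curtis)
    elif metric == "jaccard":
        d = _pairwise(x, _jaccard)
    elif metric == "jensen_shannon":
        d = _pairwise(x, lambda a, b: _jensen_shannon(a, b, jsd_sqrt))
    else:
        if tree is None:
            raise ValueError("UniFrac metrics require a phylogenetic tree")
        edges = _TreeEdges(_as_tree(tree), list(abundances.columns))
        totals = x.sum(axis=1, keepdims=True)
        props = np.divide(x, totals, out=np.zeros_like(x), where=totals > 0)
        if metric == "unifrac_weighted":
            flows = props @ edges.m.T  # samples x edges: fraction descending each edge
            def wu(i_flow, j_flow):
                denom = (edges.b * (i_flow + j_flow)).sum()
                return 0.0 if denom == 0 else (edges.b * np.abs(i_flow - j_flow)).sum() / denom
            d = _pairwise(flows, wu)
        else:
            present = (x > 0) @ edges.m.T > 0  # samples x edges
            def uu(pi, pj):
                either = (pi | pj)
                total = (edges.b * either).sum()
                unshared = (edges.b * (pi ^ pj)).sum()
                return 0.0 if total == 0 else unshared / total
            d = _pairwise(present, uu)
    return DistanceMatrix(ids=ids, d=d, metric_name=metric)


# ---------------------------------------------------------------- PERMANOVA

@dataclass
class PermanovaTerm:
    term: str
    df: int
    ss: float
    pseudo_f: float
    r2: float
    p_value: float


@dataclass
class PermanovaResult:
    terms: dict[str, PermanovaTerm]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_permutations: int
    scheme: str = "free_permutation_of_observations"
    dropped_samples: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "terms": {
                k: {
                    "df": t.df,
                    "ss": t.ss,
                    "pseudo_f": t.pseudo_f,
                    "r2": t.r2,
                    "p_value": t.p_value,
                }
                for k, t in self.terms.items()
            },
            "residual_df": self.residual_df,
            "residual_ss": self.residual_ss,
            "total_ss": self.total_ss,
            "n_permutations": self.n_permutations,
            "scheme": self.scheme,
            "dropped_samples": self.dropped_samples,
        }


def _design_blocks(design: pd.DataFrame) -> dict[str, np.ndarray]:
    """Encode each design column as a block: numeric as-is, categorical dummy."""
    blocks = {}
    for col in design.columns:
        s = design[col]
        if pd.api.types.is_numeric_dtype(s):
            arr = s.to_numpy(dtype=float).reshape(-1, 1)
            if np.ptp(arr) == 0:
                raise ValueError(f"term {col!r} is constant")
        else:
            dummies = pd.get_dummies(s.astype(str), drop_first=True)
            if dummies.shape[1] == 0:
                raise ValueError(f"term {col!r} is constant")
            arr = dummies.to_numpy(dtype=float)
        blocks[col] = arr
    return blocks


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto col(x) via pseudo-inverse, and rank of x."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = s.max() * max(x.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    u = u[:, :rank]
    return u @ u.T, rank


def gower_center(d: np.ndarray) -> np.ndarray:
    """G = -1/2 J D^2 J with J the centering matrix."""
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def permanova_marginal(
    dist: DistanceMatrix,
    design: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Marginal (type III) PERMANOVA of every design column.

    Each term's sum of squares is SS(full) - SS(full minus that term) on the
    Gower-centered matrix; pseudo-F uses the full-model residual.  p-values
    come from free permutation of observations with the (1 + exceed)/(1 + n)
    convention, ties counting toward the numerator.  With ``exhaustive`` the
    permutation distribution enumerates all n! relabelings (identity
    included) and p = #{F* >= F_obs} / n!.
    """
    design = design.loc[list(dist.ids)] if set(design.index) >= set(dist.ids) else design
    if len(design) != len(dist.ids):
        raise ValueError("design must cover every sample in the distance matrix")
    complete = design.notna().all(axis=1).to_numpy()
    dropped = [i for i, ok in zip(dist.ids, complete) if not ok]
    design = design.loc[complete]
    d = dist.d[np.ix_(complete, complete)]
    n = d.shape[0]
    if n_perm < 99 and not exhaustive:
        raise ValueError("n_perm must be >= 99")

    blocks = _design_blocks(design)
    intercept = np.ones((n, 1))
    x_full = np.hstack([intercept] + list(blocks.values()))
    h_full, rank_full = _hat(x_full)
    if rank_full >= n:
        raise ValueError("design is saturated: no residual degrees of freedom")
    df_res = n - rank_full

    g = gower_center(d)
    ss_total = float(np.trace(g))
    ss_full = float(np.sum(h_full * g))  # tr(H G), H symmetric idempotent
    ss_res_full = ss_total - ss_full

    # Per-term reduced models; marginal SS and F as functionals of G so the
    # same hat matrices can be reused for every permutation of G.
    reduced = {}
    for term in blocks:
        x_red = np.hstack(
            [intercept] + [blocks[t] for t in blocks if t != term]
        )
        h_red, rank_red = _hat(x_red)
        df_t = rank_full - rank_red
        if df_t == 0:
            raise ValueError(f"term {term!r} adds no rank to the design")
        reduced[term] = (h_red, df_t)

    def stats_for(gp: np.ndarray) -> dict[str, float]:
        ssf = float(np.sum(h_full * gp))
        res = float(np.trace(gp)) - ssf
        out = {}
        for term, (h_red, df_t) in reduced.items():
            ss_t = ssf - float(np.sum(h_red * gp))
            out[term] = (ss_t / df_t) / (res / df_res) if res > 0 else np.inf
        return out

    f_obs = stats_for(g)

    if exhaustive:
        perms = list(itertools.permutations(range(n)))
        exceed = {t: 0 for t in blocks}
        for perm in perms:
            idx = np.asarray(perm)
            fs = stats_for(g[np.ix_(idx, idx)])
            for t in blocks:
                if fs[t] >= f_obs[t] - 1e-12:
                    exceed[t] += 1
        n_used = len(perms)
        p_vals = {t: exceed[t] / n_used for t in blocks}
    else:
        rng = np.random.default_rng(seed)
        exceed = {t: 0 for t in blocks}
        for _ in range(n_perm):
            idx = rng.permutation(n)
            fs = stats_for(g[np.ix_(idx, idx)])
            for t in blocks:
                if fs[t] >= f_obs[t] - 1e-12:
                    exceed[t] += 1
        n_used = n_perm
        p_vals = {t: (1 + exceed[t]) / (1 + n_perm) for t in blocks}

    terms = {}
    for term, (h_red, df_t) in reduced.items():
        ss_t = ss_full - float(np.sum(h_red * g))
        terms[term] = PermanovaTerm(
            term=term,
            df=df_t,
            ss=ss_t,
            pseudo_f=f_obs[term],
            r2=ss_t / ss_total if ss_total > 0 else 0.0,
            p_value=p_vals[term],
        )
    return PermanovaResult(
        terms=terms,
        residual_df=df_res,
        residual_ss=ss_res_full,
        total_ss=ss_total,
        n_permutations=n_used,
        scheme="exhaustive_enumeration" if exhaustive else "free_permutation_of_observations",
        dropped_samples=dropped,
    )
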