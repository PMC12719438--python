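"""Synthetic multi-cohort vaginal 16S data with known ground truth.

Emulates the structure of five published endometrial-cancer case-control
cohorts: per-cohort sample sizes and label balance (22, 149, 36, 27, 31
samples; 130 benign / 135 EC overall), cohort-specific batch effects on
composition, higher alpha diversity in EC samples, a small set of
*Peptoniphilus*-like taxa enriched in EC across cohorts, covariate effects
(age, BMI, ethnicity, vaginal pH) on composition, and the per-cohort
covariate availability pattern of the real studies (one cohort with age
only, one with no patient metadata).

Generative model, per sample: a global base log-composition (dominated by a
*Lactobacillus*-like genus) is perturbed by a per-cohort log-normal batch
effect, linear covariate effects on the log-relative-abundance scale, an
EC-specific log fold change on the designated enriched taxa, and — for EC
samples — a tempering of the logits that flattens the expected composition
(hence higher Shannon entropy).  Proportions are drawn from a Dirichlet
around the resulting composition (Dirichlet-multinomial overdispersion) and
counts multinomially at a Poisson sequencing depth.  Vaginal pH is a
deterministic-plus-noise function of the *Lactobacillus* fraction,
dichotomized at 4.5.  The global seed expands into one child seed stream for
shared structure plus one per cohort via ``numpy`` ``SeedSequence.spawn``,
so appending a cohort never perturbs earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

ALL_COVARIATES = ("age", "bmi", "ethnicity", "ph")

_DEFAULT_COHORTS = ("antonio", "walsh", "tsementzi", "chao", "gressel")
_DEFAULT_SIZES = (22, 149, 36, 27, 31)
_DEFAULT_EC = (12, 69, 8, 23, 23)
# per-cohort (benign, EC) means for age / BMI; values for the cohorts that
# report them, field-typical values otherwise
_AGE_MEANS = {
    "antonio": (47.1, 62.3),
    "walsh": (50.4, 61.3),
    "tsementzi": (63.7, 61.1),
    "chao": (52.0, 58.0),
    "gressel": (44.6, 44.4),
}
_AGE_SDS = {"antonio": 9.0, "walsh": 10.5, "tsementzi": 6.0, "chao": 8.0, "gressel": 11.5}
_BMI_MEANS = {
    "antonio": (29.2, 34.8),
    "walsh": (31.7, 35.6),
    "tsementzi": (27.1, 32.0),
    "chao": (24.0, 27.0),
    "gressel": (28.0, 33.0),
}
_BMI_SD = 7.5
_WHITE_PROB = {"benign": 0.72, "EC": 0.85}
_PH_MISSING = {"benign": 0.08, "EC": 0.2}

_NAMED_GENERA = (
    "Prevotella",
    "Streptococcus",
    "Blautia",
    "Porphyromonas",
    "Peptostreptococcus",
)


def _default_missingness() -> dict[str, tuple[str, ...]]:
    return {
        "antonio": ALL_COVARIATES,
        "walsh": ALL_COVARIATES,
        "tsementzi": ALL_COVARIATES,
        "chao": ("age",),
        "gressel": (),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model; defaults mirror the five-cohort design."""

    cohort_ids: tuple[str, ...] = _DEFAULT_COHORTS
    cohort_sizes: tuple[int, ...] = _DEFAULT_SIZES
    ec_counts: tuple[int, ...] = _DEFAULT_EC
    n_taxa: int = 120
    n_ec_enriched_taxa: int = 5
    ec_log_fold_change: float = 1.5
    batch_effect_sd: float = 1.0
    covariate_effect_sizes: dict = field(
        default_factory=lambda: {"age": 0.3, "bmi": 0.2, "ethnicity": 0.3}
    )
    missingness_plan: dict = field(default_factory=_default_missingness)
    diversity_shift: float = 0.3
    sequencing_depth_mean: int = 10_000
    dirichlet_concentration: float = 50.0
    seed: int = 0
    held_out: str = "antonio"

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_ids)

    @property
    def ec_fractions(self) -> tuple[float, ...]:
        return tuple(e / s for e, s in zip(self.ec_counts, self.cohort_sizes))

    def validate(self) -> None:
        if not (
            len(self.cohort_sizes) == len(self.ec_counts) == len(self.cohort_ids)
        ):
            raise ValueError("cohort_ids, cohort_sizes and ec_counts must align")
        if any(s < 1 for s in self.cohort_sizes):
            raise ValueError("cohort sizes must be positive")
        if any(not 0 <= e <= s for e, s in zip(self.ec_counts, self.cohort_sizes)):
            raise ValueError("EC counts must lie in [0, cohort size]")
        if not 0 <= self.n_ec_enriched_taxa <= self.n_taxa:
            raise ValueError("n_ec_enriched_taxa must be <= n_taxa")
        if self.batch_effect_sd < 0 or self.diversity_shift < 0:
            raise ValueError("batch_effect_sd and diversity_shift must be >= 0")
        if self.sequencing_depth_mean < 1:
            raise ValueError("sequencing_depth_mean must be positive")
        for cid, size, ec in zip(self.cohort_ids, self.cohort_sizes, self.ec_counts):
            # a training cohort of < 2 samples is necessarily single-class
            if cid != self.held_out and size < 2:
                raise ValueError(
                    f"training cohort {cid!r} with < 2 samples would be "
                    "single-class"
                )
        if set(self.missingness_plan) != set(self.cohort_ids):
            raise ValueError("missingness_plan must name every cohort")


@dataclass
class CohortDataset:
    """One study's counts, taxonomy, labels and (possibly partial) metadata."""

    cohort_id: str
    counts: pd.DataFrame  # samples x taxa, non-negative ints
    taxonomy: pd.Series  # taxon id -> lineage string
    labels: pd.Series  # 'benign' / 'EC'
    covariates: pd.DataFrame  # age, bmi, ethnicity, ph (NaN where missing)
    tree: str | None = None  # newick over taxa

    @property
    def available_covariates(self) -> list[str]:
        return [c for c in self.covariates.columns if self.covariates[c].notna().any()]

    def validate(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts")
        if (arr.sum(axis=1) <= 0).any():
            raise ValueError("sample with zero total count")


@dataclass
class MultiCohortStudy:
    cohorts: list[CohortDataset]
    held_out: str
    taxonomy: pd.Series
    tree: str
    config: SimulationConfig | None = None
    enriched_taxa: list[str] = field(default_factory=list)

    def get(self, cohort_id: str) -> CohortDataset:
        for c in self.cohorts:
            if c.cohort_id == cohort_id:
                return c
        raise KeyError(cohort_id)

    @property
    def cohort_ids(self) -> list[str]:
        return [c.cohort_id for c in self.cohorts]

    def training_cohorts(self) -> list[CohortDataset]:
        return [c for c in self.cohorts if c.cohort_id != self.held_out]

    def held_out_cohort(self) -> CohortDataset:
        return self.get(self.held_out)

    def with_held_out(self, cohort_id: str) -> "MultiCohortStudy":
        if cohort_id not in self.cohort_ids:
            raise KeyError(cohort_id)
        return MultiCohortStudy(
            cohorts=self.cohorts,
            held_out=cohort_id,
            taxonomy=self.taxonomy,
            tree=self.tree,
            config=self.config,
            enriched_taxa=self.enriched_taxa,
        )

    def pooled(self, which: str = "all"):
        """Concatenated counts / labels / covariates / cohort tags."""
        sel = (
            self.cohorts
            if which == "all"
            else self.training_cohorts()
            if which == "training"
            else [self.held_out_cohort()]
        )
        counts = pd.concat([c.counts for c in sel])
        labels = pd.concat([c.labels for c in sel])
        covs = pd.concat([c.covariates for c in sel])
        batch = pd.concat(
            [pd.Series(c.cohort_id, index=c.counts.index) for c in sel]
        ).rename("cohort")
        return counts, labels, covs, batch


# ------------------------------------------------------------------ taxonomy

def make_taxonomy(n_taxa: int, n_enriched: int) -> tuple[pd.Series, list[str], list[str], list[str]]:
    """Deterministic species-level taxonomy over ``n_taxa`` taxa.

    Returns (taxonomy, taxon_ids, lactobacillus_taxa, enriched_taxa).  The
    first four taxa are *Lactobacillus* species, the next ``n_enriched`` are
    *Peptoniphilus* species (the EC-enriched set), a handful belong to other
    named genera with two species each, two are genus-unassigned (exercising
    the aggregation fallback), and the rest are singleton genera.
    """
    if n_taxa < 4 + n_enriched + 2:
        raise ValueError("n_taxa too small for the taxonomy template")
    ids, lineages = [], []
    lacto, enriched = [], []
    i = 0
    for sp in range(4):
        tid = f"t{i:03d}"
        ids.append(tid)
        lineages.append(
            f"d__Bacteria;f__Lactobacillaceae;g__Lactobacillus;s__Lactobacillus_sp{sp}"
        )
        lacto.append(tid)
        i += 1
    for sp in range(n_enriched):
        tid = f"t{i:03d}"
        ids.append(tid)
        lineages.append(
            f"d__Bacteria;f__Peptoniphilaceae;g__Peptoniphilus;s__Peptoniphilus_sp{sp}"
        )
        enriched.append(tid)
        i += 1
    for genus in _NAMED_GENERA:
        for sp in range(2):
            if i >= n_taxa:
                break
            ids.append(f"t{i:03d}")
            lineages.append(f"d__Bacteria;f__{genus}aceae;g__{genus};s__{genus}_sp{sp}")
            i += 1
    for k in range(2):
        if i >= n_taxa:
            break
        ids.append(f"t{i:03d}")
        lineages.append(f"d__Bacteria;f__Clostridiaceae;g__;s__")
        i += 1
    g = 0
    while i < n_taxa:
        ids.append(f"t{i:03d}")
        lineages.append(f"d__Bacteria;f__Family_{g};g__Genus_{g};s__Genus_{g}_sp0")
        i += 1
        g += 1
    return pd.Series(lineages, index=ids, name="lineage"), ids, lacto, enriched


# ------------------------------------------------------------------ tree

def simulate_tree(n_taxa: int, seed: int = 0, taxon_ids: list[str] | None = None) -> str:
    """Random bifurcating tree with positive branch lengths, as Newick.

    Leaves are named ``t000..`` (or ``taxon_ids`` when given); built by
    random sequential pair-joining.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa for a tree")
    rng = np.random.default_rng(seed)
    if taxon_ids is None:
        taxon_ids = [f"t{i:03d}" for i in range(n_taxa)]
    if len(taxon_ids) != n_taxa:
        raise ValueError("taxon_ids length must equal n_taxa")
    nodes = [f"{t}:{rng.uniform(0.1, 1.0):.5f}" for t in taxon_ids]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = rng.uniform(0.1, 1.0)
        merged = f"({nodes[i]},{nodes[j]}):{b:.5f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


# ------------------------------------------------------------------ simulate

def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def simulate_multicohort(config: SimulationConfig) -> MultiCohortStudy:
    """Draw a full multi-cohort study from the generative model."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    global_ss, *cohort_ss = root.spawn(1 + config.n_cohorts)
    grng = np.random.default_rng(global_ss)

    taxonomy, taxon_ids, lacto, enriched = make_taxonomy(
        config.n_taxa, config.n_ec_enriched_taxa
    )
    lacto_idx = [taxon_ids.index(t) for t in lacto]
    enr_idx = [taxon_ids.index(t) for t in enriched]

    base = grng.normal(0.0, 1.0, size=config.n_taxa)
    base[lacto_idx] = np.array([5.5, 4.0, 3.5, 3.0])  # Lactobacillus dominance
    loadings = {}
    for cov in ("age", "bmi", "ethnicity"):
        w = np.zeros(config.n_taxa)
        hit = grng.random(config.n_taxa) < 0.2
        w[hit] = grng.normal(0.0, 1.0, size=hit.sum())
        w[lacto_idx[0]] = -abs(w[lacto_idx[0]]) - 0.5  # older/higher-BMI -> less Lactobacillus
        loadings[cov] = w
    tree = simulate_tree(config.n_taxa, seed=int(grng.integers(2**31)), taxon_ids=taxon_ids)

    cohorts = []
    for (cid, size, n_ec, ss) in zip(
        config.cohort_ids, config.cohort_sizes, config.ec_counts, cohort_ss
    ):
        rng = np.random.default_rng(ss)
        labels = np.array(["EC"] * n_ec + ["benign"] * (size - n_ec))
        rng.shuffle(labels)
        batch_shift = rng.normal(0.0, config.batch_effect_sd, size=config.n_taxa)

        age_mu = _AGE_MEANS[cid] if cid in _AGE_MEANS else (50.0, 60.0)
        age_sd = _AGE_SDS.get(cid, 10.0)
        bmi_mu = _BMI_MEANS[cid] if cid in _BMI_MEANS else (28.0, 33.0)
        is_ec = labels == "EC"
        age = rng.normal(np.where(is_ec, age_mu[1], age_mu[0]), age_sd)
        bmi = rng.normal(np.where(is_ec, bmi_mu[1], bmi_mu[0]), _BMI_SD)
        white_p = np.where(is_ec, _WHITE_PROB["EC"], _WHITE_PROB["benign"])
        ethnicity = np.where(rng.random(size) < white_p, "White", "Other")

        eff = config.covariate_effect_sizes
        age_z = (age - 55.0) / 10.0
        bmi_z = (bmi - 30.0) / 7.0
        eth_z = (ethnicity == "Other").astype(float)

        counts = np.zeros((size, config.n_taxa), dtype=int)
        lacto_fraction = np.zeros(size)
        for s in range(size):
            z = base + batch_shift
            z = z + eff.get("age", 0.0) * age_z[s] * loadings["age"]
            z = z + eff.get("bmi", 0.0) * bmi_z[s] * loadings["bmi"]
            z = z + eff.get("ethnicity", 0.0) * eth_z[s] * loadings["ethnicity"]
            if is_ec[s]:
                z = z / (1.0 + config.diversity_shift)  # flatter -> higher Shannon
                z[enr_idx] = z[enr_idx] + config.ec_log_fold_change
            alpha = config.dirichlet_concentration * _softmax(z)
            p = rng.dirichlet(np.maximum(alpha, 1e-6))
            lacto_fraction[s] = p[lacto_idx].sum()
            depth = max(int(rng.poisson(config.sequencing_depth_mean)), 50)
            counts[s] = rng.multinomial(depth, p)

        ph_cont = 7.0 - 3.5 * lacto_fraction + rng.normal(0.0, 0.3, size)
        ph = np.where(ph_cont <= 4.5, "<=4.5", ">4.5")

        sample_ids = [f"{cid}_{s:03d}" for s in range(size)]
        cov = pd.DataFrame(
            {"age": age, "bmi": bmi, "ethnicity": ethnicity, "ph": ph},
            index=sample_ids,
        )
        # per-cohort availability plan, then MAR label-dependent pH dropout
        available = set(config.missingness_plan[cid])
        for col in ALL_COVARIATES:
            if col not in available:
                cov[col] = np.nan
        if "ph" in available:
            miss_p = np.where(is_ec, _PH_MISSING["EC"], _PH_MISSING["benign"])
            drop = rng.random(size) < miss_p
            cov.loc[drop, "ph"] = np.nan

        cohort = CohortDataset(
            cohort_id=cid,
            counts=pd.DataFrame(counts, index=sample_ids, columns=taxon_ids),
            taxonomy=taxonomy,
            labels=pd.Series(labels, index=sample_ids, name="diagnosis"),
            covariates=cov,
            tree=tree,
        )
        cohort.validate()
        cohorts.append(cohort)

    return MultiCohortStudy(
        cohorts=cohorts,
        held_out=config.held_out,
        taxonomy=taxonomy,
        tree=tree,
        config=config,
        enriched_taxa=enriched,
    )


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Config with no disease signal: no enrichment, no diversity shift,
    no covariate-composition coupling (covariate *distributions* still differ
    by label unless overridden)."""
    base = SimulationConfig(
        ec_log_fold_change=0.0,
        diversity_shift=0.0,
        covariate_effect_sizes={},
        seed=seed,
    )
    return replace(base, **overrides)


# ------------------------------------------------------------------ I/O

def write_study(study: MultiCohortStudy, out_dir) -> None:
    """Write per-cohort TSV counts + CSV metadata, taxonomy, tree, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "held_out": study.held_out,
        "cohorts": [],
        "enriched_taxa": study.enriched_taxa,
    }
    study.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t")
    (out / "tree.nwk").write_text(study.tree + "\n")
    for c in study.cohorts:
        c.counts.to_csv(out / f"{c.cohort_id}_counts.tsv", sep="\t")
        meta = c.covariates.copy()
        meta.insert(0, "diagnosis", c.labels)
        meta.to_csv(out / f"{c.cohort_id}_metadata.csv", na_rep="NA")
        manifest["cohorts"].append(
            {
                "cohort_id": c.cohort_id,
                "n_samples": int(len(c.counts)),
                "n_ec": int((c.labels == "EC").sum()),
                "available_covariates": c.available_covariates,
            }
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_study(in_dir) -> MultiCohortStudy:
    """Round-trip reader for :func:`write_study` output."""
    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    taxonomy = pd.read_csv(src / "taxonomy.tsv", sep="\t", index_col=0)["lineage"]
    tree = (src / "tree.nwk").read_text().strip()
    cohorts = []
    for entry in manifest["cohorts"]:
        cid = entry["cohort_id"]
        counts = pd.read_csv(src / f"{cid}_counts.tsv", sep="\t", index_col=0)
        meta = pd.read_csv(
            src / f"{cid}_metadata.csv", index_col=0, na_values=["NA"],
            keep_default_na=True, dtype={"ethnicity": "object", "ph": "object"},
        )
        labels = meta["diagnosis"]
        cov = meta.drop(columns=["diagnosis"])
        cohorts.append(
            CohortDataset(
                cohort_id=cid,
                counts=counts,
                taxonomy=taxonomy,
                labels=labels,
                covariates=cov,
                tree=tree,
            )
        )
    return MultiCohortStudy(
        cohorts=cohorts,
        held_out=manifest["held_out"],
        taxonomy=taxonomy,
        tree=tree,
        enriched_taxa=manifest.get("enriched_taxa", []),
    )
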