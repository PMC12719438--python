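"""Count-table preprocessing: genus aggregation, prevalence filtering, CLR.

The model-ready representation is fixed: species/ASV counts are aggregated to
genus, taxa present in fewer than 5% of samples are removed (presence at
exactly the threshold is kept), and the surviving counts are mapped through
the centered log-ratio transform.  The order is aggregation -> filter -> CLR;
the filter is always learned on training samples and frozen before being
applied to evaluation data so that feature selection cannot leak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TAXON = "taxon"
NUMERIC_COVARIATE = "numeric_covariate"
CATEGORICAL_COVARIATE = "categorical_covariate"

_RANK_ORDER = ("d", "k", "p", "c", "o", "f", "g", "s")


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a semicolon-delimited lineage with rank prefixes into a rank map.

    Ranks with an empty name after the ``x__`` prefix are treated as
    unassigned and omitted.
    """
    out: dict[str, str] = {}
    for part in lineage.split(";"):
        part = part.strip()
        if "__" in part:
            rank, name = part.split("__", 1)
            if name:
                out[rank] = name
    return out


def genus_label(lineage: str) -> str:
    """Genus name for a lineage, falling back to the deepest resolved ancestor.

    Taxa unassigned at genus are grouped under ``<rank>_<name>_unclassified``
    so they stay distinguishable from true genera of the same name.
    """
    ranks = parse_lineage(lineage)
    if "g" in ranks:
        return ranks["g"]
    for rank in reversed(_RANK_ORDER[:-2]):  # deepest resolved above genus
        if rank in ranks:
            return f"{rank}_{ranks[rank]}_unclassified"
    return "unclassified"


def aggregate_to_genus(counts: pd.DataFrame, taxonomy: pd.Series) -> pd.DataFrame:
    """Sum count columns that share a genus; per-sample totals are conserved."""
    missing = [t for t in counts.columns if t not in taxonomy.index]
    if missing:
        raise ValueError(f"taxonomy missing for taxa: {missing[:5]}")
    labels = counts.columns.map(lambda t: genus_label(taxonomy.loc[t]))
    out = counts.T.groupby(labels, sort=True).sum().T
    out.index = counts.index
    return out


def prevalence_filter(counts: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Drop taxa present (count > 0) in fewer than ``threshold`` of samples.

    "Fewer than" is strict: a taxon present in exactly threshold * n samples
    survives.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    prevalence = (counts > 0).mean(axis=0)
    return counts.loc[:, prevalence >= threshold]


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"samples with zero total count: {list(zero.index)[:5]}")
    return counts.div(totals, axis=0)


def clr_transform(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform: ln(x+c) centered by the sample mean log.

    Rows sum to zero exactly (up to float error).  Scale invariance to
    per-sample sequencing depth holds only in the limit of counts much larger
    than the pseudocount.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if counts.shape[1] == 0:
        return counts.astype(float).copy()
    logged = np.log(counts.to_numpy(dtype=float) + pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=counts.index, columns=counts.columns)


@dataclass
class FeatureMatrix:
    """Model-ready samples x features block with per-feature kind tags.

    ``values`` holds CLR-transformed taxon columns plus covariate columns;
    ``feature_kinds`` tags each column as taxon / numeric_covariate /
    categorical_covariate so downstream resampling and imputation know which
    distance and model family to use per column.
    """

    values: pd.DataFrame
    feature_kinds: dict[str, str]
    labels: pd.Series
    frozen_taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = set(self.feature_kinds) - set(self.values.columns)
        if unknown:
            raise ValueError(f"feature_kinds refer to unknown columns: {unknown}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def taxon_columns(self) -> list[str]:
        return [c for c, k in self.feature_kinds.items() if k == TAXON]

    def covariate_columns(self) -> list[str]:
        return [c for c, k in self.feature_kinds.items() if k != TAXON]

    def subset_columns(self, columns: list[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[columns].copy(),
            feature_kinds={c: self.feature_kinds[c] for c in columns},
            labels=self.labels.copy(),
            frozen_taxa=[c for c in self.frozen_taxa if c in columns],
        )

    def to_tsv(self, path, sidecar_json=None) -> None:
        self.values.to_csv(path, sep="\t")
        if sidecar_json is not None:
            with open(sidecar_json, "w") as fh:
                json.dump(
                    {"feature_kinds": self.feature_kinds, "frozen_taxa": self.frozen_taxa},
                    fh,
                    indent=2,
                )


def build_feature_matrix(
    counts: pd.DataFrame,
    taxonomy: pd.Series,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    covariate_kinds: dict[str, str] | None = None,
    prevalence_threshold: float = 0.05,
    pseudocount: float = 0.5,
    frozen_taxa: list[str] | None = None,
) -> FeatureMatrix:
    """Aggregate -> filter -> CLR, then append covariate columns.

    When ``frozen_taxa`` is given (evaluation data), the prevalence filter is
    NOT re-learned: the training-time taxon list is applied verbatim, with
    absent taxa filled as zero counts.
    """
    genus = aggregate_to_genus(counts, taxonomy)
    if frozen_taxa is None:
        filtered = prevalence_filter(genus, prevalence_threshold)
        kept = list(filtered.columns)
    else:
        kept = list(frozen_taxa)
        filtered = genus.reindex(columns=kept, fill_value=0)
    clr = clr_transform(filtered, pseudocount)
    kinds = {c: TAXON for c in clr.columns}
    blocks = [clr]
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.loc[clr.index]
        for c in cov.columns:
            kind = (covariate_kinds or {}).get(
                c,
                NUMERIC_COVARIATE
                if pd.api.types.is_numeric_dtype(cov[c])
                else CATEGORICAL_COVARIATE,
            )
            kinds[c] = kind
        blocks.append(cov)
    values = pd.concat(blocks, axis=1)
    return FeatureMatrix(
        values=values,
        feature_kinds=kinds,
        labels=labels.loc[clr.index],
        frozen_taxa=kept,
    )
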