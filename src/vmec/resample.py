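"""Class rebalancing for mixed feature types and chained-equation imputation.

Case/control imbalance inside a training fold is corrected by SMOTE for
nominal+continuous data (SMOTE-NC): synthetic minority samples interpolate
numeric features between a minority seed and one of its k nearest minority
neighbors, while categorical features take the majority vote among those
neighbors; the neighbor metric adds the squared median numeric standard
deviation once per differing category.

Missing covariates are completed by chained equations: each incomplete
column is cycled through a per-column model (ridge regression for numeric,
logistic regression for categorical) conditioned on the other covariates and
the microbiome features.  Models fit on training data are frozen and reused
to complete evaluation data, and observed cells are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, RidgeCV


@dataclass
class RebalancePlan:
    k_neighbors: int = 5
    target_ratio: float = 1.0
    categorical_features: list[str] = field(default_factory=list)
    seed: int = 0


def smote_nc(
    features: pd.DataFrame, labels: pd.Series, plan: RebalancePlan
) -> tuple[pd.DataFrame, pd.Series]:
    """Oversample the minority class to target_ratio x majority size.

    Returns the input rows followed by the synthetic minority rows.  Numeric
    features must be finite; both classes must be present with a minority of
    at least 2 samples.
    """
    labels = labels.loc[features.index]
    counts = labels.value_counts()
    if len(counts) != 2:
        raise ValueError("need exactly two classes")
    minority_label = counts.idxmin()
    majority_n, minority_n = counts.max(), counts.min()
    if minority_n < 2:
        raise ValueError("minority class must have >= 2 samples")

    num_cols = [c for c in features.columns if c not in plan.categorical_features]
    if not np.isfinite(features[num_cols].to_numpy(float)).all():
        raise ValueError("numeric features must be finite")

    n_target = int(np.ceil(plan.target_ratio * majority_n))
    n_synth = max(n_target - minority_n, 0)
    if n_synth == 0:
        return features.copy(), labels.copy()

    minority = features.loc[labels == minority_label]
    x_num = minority[num_cols].to_numpy(float)
    x_cat = minority[plan.categorical_features].astype(str).to_numpy()

    # nominal penalty: squared median of numeric stds per differing category
    stds = x_num.std(axis=0, ddof=0)
    med = float(np.median(stds)) if len(num_cols) else 1.0

    diff = x_num[:, None, :] - x_num[None, :, :]
    d2 = (diff**2).sum(axis=2)
    if x_cat.shape[1]:
        mismatch = (x_cat[:, None, :] != x_cat[None, :, :]).sum(axis=2)
        d2 = d2 + mismatch * med**2
    np.fill_diagonal(d2, np.inf)
    k = min(plan.k_neighbors, minority_n - 1)
    neighbors = np.argsort(d2, axis=1)[:, :k]

    rng = np.random.default_rng(plan.seed)
    seeds = rng.integers(0, minority_n, size=n_synth)
    synth_num = np.empty((n_synth, len(num_cols)))
    synth_cat = np.empty((n_synth, x_cat.shape[1]), dtype=object)
    for s in range(n_synth):
        i = seeds[s]
        j = neighbors[i, rng.integers(0, k)]
        lam = rng.uniform()
        synth_num[s] = x_num[i] + lam * (x_num[j] - x_num[i])
        for c in range(x_cat.shape[1]):
            vals, cnts = np.unique(x_cat[neighbors[i], c], return_counts=True)
            synth_cat[s, c] = vals[np.argmax(cnts)]

    synth = pd.DataFrame(synth_num, columns=num_cols)
    for ci, c in enumerate(plan.categorical_features):
        synth[c] = synth_cat[:, ci]
    synth = synth[features.columns]
    synth.index = [f"synthetic_{minority_label}_{i}" for i in range(n_synth)]
    out_x = pd.concat([features, synth], axis=0)
    out_y = pd.concat(
        [labels, pd.Series(minority_label, index=synth.index, name=labels.name)]
    )
    return out_x, out_y


class ChainedImputer:
    """MICE-style single-completion imputer with frozen per-column models.

    Numeric covariates are imputed with ridge regression, categorical ones
    with logistic regression, each conditioned on the other (currently
    completed) covariates and the microbiome feature block.  ``fit_transform``
    learns the models on training data; ``transform`` reuses them unchanged.
    """

    def __init__(self, n_iterations: int = 5, seed: int = 0):
        self.n_iterations = n_iterations
        self.seed = seed
        self._models: dict[str, object] = {}
        self._init_values: dict[str, object] = {}
        self._categories: dict[str, list[str]] = {}
        self._columns: list[str] | None = None
        self._cat_cols: list[str] = []
        self._scaler: dict[str, tuple] = {}

    # -- encoding helpers ------------------------------------------------
    def _encode_predictors(
        self, cov: pd.DataFrame, micro: pd.DataFrame | None, exclude: str
    ) -> np.ndarray:
        blocks = []
        for c in self._columns:
            if c == exclude:
                continue
            if c in self._cat_cols:
                cats = self._categories[c]
                codes = pd.Categorical(cov[c].astype(str), categories=cats)
                blocks.append(pd.get_dummies(codes).to_numpy(float))
            else:
                blocks.append(cov[c].to_numpy(float).reshape(-1, 1))
        if micro is not None and micro.shape[1] > 0:
            blocks.append(micro.to_numpy(float))
        if not blocks:
            return np.ones((len(cov), 1))
        x = np.hstack(blocks)
        # z-scale with frozen training moments so the ridge penalty is
        # comparable across predictor blocks
        if exclude not in self._scaler:
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            self._scaler[exclude] = (mu, sd)
        mu, sd = self._scaler[exclude]
        return (x - mu) / sd

    def _initial_fill(self, cov: pd.DataFrame) -> pd.DataFrame:
        filled = cov.copy()
        for c in self._columns:
            mask = filled[c].isna()
            if mask.any():
                filled.loc[mask, c] = self._init_values[c]
        return filled

    # -- fitting ---------------------------------------------------------
    def fit_transform(
        self, covariates: pd.DataFrame, microbiome: pd.DataFrame | None = None
    ) -> pd.DataFrame:
        cov = covariates.copy()
        self._columns = list(cov.columns)
        self._cat_cols = [
            c for c in cov.columns if not pd.api.types.is_numeric_dtype(cov[c])
        ]
        for c in self._columns:
            if cov[c].isna().all():
                raise ValueError(
                    f"covariate {c!r} is entirely missing: exclude it for this "
                    "cohort instead of imputing cross-cohort"
                )
            if c in self._cat_cols:
                self._init_values[c] = cov[c].mode(dropna=True).iloc[0]
                self._categories[c] = sorted(cov[c].dropna().astype(str).unique())
            else:
                self._init_values[c] = float(cov[c].mean(skipna=True))

        missing_cols = [c for c in self._columns if cov[c].isna().any()]
        observed = {c: cov[c].notna().to_numpy() for c in missing_cols}
        filled = self._initial_fill(cov)
        if not missing_cols:
            return filled

        for _ in range(self.n_iterations):
            for c in missing_cols:
                x = self._encode_predictors(filled, microbiome, exclude=c)
                obs = observed[c]
                if c in self._cat_cols:
                    y_obs = cov.loc[obs, c].astype(str)
                    if y_obs.nunique() < 2:
                        model = _ConstantModel(y_obs.iloc[0])
                    else:
                        model = LogisticRegression(max_iter=500)
                        model.fit(x[obs], y_obs)
                    filled.loc[~obs, c] = model.predict(x[~obs])
                else:
                    # LOO-CV ridge: the penalty adapts to however wide the
                    # microbiome predictor block is
                    model = RidgeCV(alphas=np.logspace(-1, 4, 11))
                    model.fit(x[obs], cov.loc[obs, c].astype(float))
                    filled.loc[~obs, c] = model.predict(x[~obs])
                self._models[c] = model
        return filled

    def transform(
        self, covariates: pd.DataFrame, microbiome: pd.DataFrame | None = None
    ) -> pd.DataFrame:
        if self._columns is None:
            raise RuntimeError("imputer is not fitted")
        cov = covariates[self._columns].copy()
        missing_cols = [c for c in self._columns if cov[c].isna().any()]
        observed = {c: cov[c].notna().to_numpy() for c in missing_cols}
        filled = self._initial_fill(cov)
        for _ in range(self.n_iterations):
            for c in missing_cols:
                model = self._models.get(c)
                if model is None:  # column complete at training time
                    continue
                x = self._encode_predictors(filled, microbiome, exclude=c)
                obs = observed[c]
                filled.loc[~obs, c] = model.predict(x[~obs])
        return filled


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, x):
        return np.full(len(x), self.value, dtype=object)


def mice_impute(
    covariates: pd.DataFrame,
    microbiome: pd.DataFrame | None = None,
    n_iterations: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """One-shot chained-equation completion of ``covariates``."""
    return ChainedImputer(n_iterations=n_iterations, seed=seed).fit_transform(
        covariates, microbiome
    )
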