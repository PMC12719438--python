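"""Classifier evaluation: confusion metrics with exact binomial CIs and AUROC.

Diagnostic studies with small held-out sets report sensitivity, specificity,
PPV and NPV with exact (Clopper-Pearson) 95% confidence intervals rather than
normal approximations, because denominators of 10-20 samples make Wald
intervals badly anti-conservative.  A metric whose denominator is zero (e.g.
NPV when the classifier never predicts "benign") is undefined and is flagged
as such with the uninformative interval [0, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

PROPORTION_METRICS = ("sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of a binary confusion matrix (positive class = disease)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=bool)
        yp = np.asarray(y_pred, dtype=bool)
        if yt.shape != yp.shape:
            raise ValueError("y_true and y_pred must have the same length")
        return cls(
            tp=int(np.sum(yt & yp)),
            fp=int(np.sum(~yt & yp)),
            tn=int(np.sum(~yt & ~yp)),
            fn=int(np.sum(yt & ~yp)),
        )


@dataclass
class MetricEstimate:
    """Point estimate with exact CI; ``undefined`` when the denominator is 0."""

    value: float | None
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int

    @property
    def undefined(self) -> bool:
        return self.value is None

    def as_dict(self) -> dict:
        return {
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "undefined": self.undefined,
        }


def exact_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact two-sided confidence interval for x successes in n trials.

    Lower bound is the alpha/2 Beta(x, n-x+1) quantile (0 when x == 0); the
    upper bound is the 1-alpha/2 Beta(x+1, n-x) quantile (1 when x == n).
    For x == n the lower bound reduces to the closed form (alpha/2)^(1/n).
    """
    if n < 1:
        raise ValueError("n must be >= 1; a zero-denominator metric is undefined")
    if not 0 <= x <= n:
        raise ValueError("x must satisfy 0 <= x <= n")
    alpha = 1.0 - level
    if x == 0:
        lower = 0.0
    elif x == n:
        lower = (alpha / 2.0) ** (1.0 / n)
    else:
        lower = float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    if x == n:
        upper = 1.0
    else:
        upper = float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return lower, upper


def _proportion_estimate(x: int, n: int, level: float) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(value=None, ci_low=0.0, ci_high=1.0, numerator=x, denominator=0)
    lo, hi = exact_ci(x, n, level)
    return MetricEstimate(value=x / n, ci_low=lo, ci_high=hi, numerator=x, denominator=n)


def confusion_metrics(counts: ConfusionCounts, level: float = 0.95) -> dict[str, MetricEstimate]:
    """Sensitivity, specificity, PPV and NPV with exact CIs.

    Each metric gets a Clopper-Pearson interval on its own numerator /
    denominator; zero-denominator metrics come back flagged undefined with
    CI [0, 1].
    """
    return {
        "sensitivity": _proportion_estimate(counts.tp, counts.tp + counts.fn, level),
        "specificity": _proportion_estimate(counts.tn, counts.tn + counts.fp, level),
        "ppv": _proportion_estimate(counts.tp, counts.tp + counts.fp, level),
        "npv": _proportion_estimate(counts.tn, counts.tn + counts.fn, level),
    }


def auroc(probabilities, labels) -> float | None:
    """Rank-based (Mann-Whitney) AUROC; ties contribute 1/2.

    Returns None (undefined) when only one class is present.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have the same length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = stats.rankdata(p)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class MetricReport:
    """Full evaluation block: confusion counts, proportion metrics, AUROC."""

    counts: ConfusionCounts
    metrics: dict[str, MetricEstimate]
    auroc: float | None
    auroc_defined: bool
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_scores(
        cls,
        y_true,
        scores,
        threshold: float = 0.5,
        level: float = 0.95,
        provenance: dict | None = None,
    ) -> "MetricReport":
        scores = np.asarray(scores, dtype=float)
        y_true = np.asarray(y_true, dtype=bool)
        # threshold rule is total: probability exactly at threshold is positive
        y_pred = scores >= threshold
        counts = ConfusionCounts.from_predictions(y_true, y_pred)
        a = auroc(scores, y_true)
        return cls(
            counts=counts,
            metrics=confusion_metrics(counts, level),
            auroc=a,
            auroc_defined=a is not None,
            provenance=provenance or {},
        )

    def as_dict(self) -> dict:
        return {
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "fn": self.counts.fn,
            },
            "metrics": {k: v.as_dict() for k, v in self.metrics.items()},
            "auroc": self.auroc,
            "auroc_defined": self.auroc_defined,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    def to_markdown(self) -> str:
        """One-row table in the style of a diagnostic-performance table."""

        def cell(est: MetricEstimate) -> str:
            if est.undefined:
                return "NaN [0, 1]"
            return f"{est.value:.2f} [{est.ci_low:.2f}, {est.ci_high:.2f}]"

        header = "| NPV | Sensitivity | PPV | Specificity | AUROC |"
        sep = "|" + "---|" * 5
        auc = "NaN" if self.auroc is None else f"{self.auroc:.2f}"
        row = (
            f"| {cell(self.metrics['npv'])} | {cell(self.metrics['sensitivity'])} "
            f"| {cell(self.metrics['ppv'])} | {cell(self.metrics['specificity'])} | {auc} |"
        )
        return "\n".join([header, sep, row])


def pool_reports(reports: list[MetricReport], y_true_all, scores_all) -> MetricReport:
    """Micro-pool confusion counts across studies; AUROC over concatenated scores."""
    tp = sum(r.counts.tp for r in reports)
    fp = sum(r.counts.fp for r in reports)
    tn = sum(r.counts.tn for r in reports)
    fn = sum(r.counts.fn for r in reports)
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    a = auroc(np.asarray(scores_all, dtype=float), np.asarray(y_true_all, dtype=bool))
    return MetricReport(
        counts=counts,
        metrics=confusion_metrics(counts),
        auroc=a,
        auroc_defined=a is not None,
        provenance={"pooled": True, "n_studies": len(reports)},
    )
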