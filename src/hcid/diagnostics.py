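"""Diagnostic-test evaluation of a two-cluster partition against diagnoses.

The clustering itself is unsupervised; evaluation cross-tabulates the
k = 2 assignment against the known binary diagnosis (positive class =
malignant by default).  Each cluster is mapped to the diagnosis class
forming its within-cluster majority, and the resulting confusion matrix
yields the standard diagnostic measures:

==============  =====================================
sensitivity     TP / (TP + FN)
specificity     TN / (TN + FP)
ppv             TP / (TP + FP)
npv             TN / (TN + FN)
lr_pos          sensitivity / (1 - specificity)
lr_neg          (1 - sensitivity) / specificity
accuracy        (TP + TN) / n
==============  =====================================

95% confidence intervals use the Clopper-Pearson exact (beta-quantile)
interval for the five proportions and the log-method
``exp(ln LR +/- z * SE(ln LR))`` of Simel et al. for the likelihood
ratios.  When any confusion cell is zero, all four cells receive a +0.5
continuity correction (Haldane-Anscombe) before the likelihood ratios and
their intervals are computed, keeping them finite; the proportions always
use the uncorrected counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionMatrix",
    "DiagnosticReport",
    "map_clusters",
    "diagnostic_report",
    "proportion_ci",
    "lr_ci",
]

MEASURES = ("sensitivity", "specificity", "ppv", "npv", "lr_pos", "lr_neg", "accuracy")


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts; the positive class is the disease (malignant)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.total < 1:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def has_zero_cell(self) -> bool:
        return min(self.tp, self.fp, self.fn, self.tn) == 0

    def corrected(self) -> tuple:
        """Counts with +0.5 added to every cell iff some cell is zero."""
        c = 0.5 if self.has_zero_cell else 0.0
        return (self.tp + c, self.fp + c, self.fn + c, self.tn + c)


def map_clusters(assignment, truth, positive=None) -> ConfusionMatrix:
    """Cross-tabulate a 2-cluster assignment with binary ground truth.

    Each cluster is declared "test positive" or "test negative" according
    to the diagnosis class of the majority of its members; if that maps
    both clusters to the same class (or ties), the one-to-one mapping
    maximizing accuracy is used instead (with a warning in the degenerate
    case).

    Parameters
    ----------
    assignment : ClusterAssignment or array of cluster labels (2 distinct)
    truth : array of binary class labels
    positive : the truth value counting as diseased. Defaults to ``"M"``
        if present, else the minority class.
    """
    labels = np.asarray(getattr(assignment, "labels", assignment))
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise ValueError("assignment and truth lengths differ")
    classes, counts = np.unique(truth, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"truth must have exactly 2 classes, got {list(classes)}")
    clusters = np.unique(labels)
    if len(clusters) != 2:
        raise ValueError(f"assignment must have exactly 2 clusters, got {list(clusters)}")
    if positive is None:
        positive = "M" if "M" in classes.astype(str) else classes[np.argmin(counts)]
    is_pos = truth.astype(str) == str(positive)
    if not is_pos.any() or is_pos.all():
        raise ValueError(f"positive class {positive!r} not a proper subset of truth")

    # majority class per cluster
    majority = {}
    for c in clusters:
        in_c = labels == c
        majority[c] = bool(is_pos[in_c].sum() * 2 > in_c.sum())
    if majority[clusters[0]] == majority[clusters[1]]:
        # degenerate: pick the accuracy-maximizing one-to-one mapping
        acc0 = ((labels == clusters[0]) == is_pos).mean()
        pos_cluster = clusters[0] if acc0 >= 1 - acc0 else clusters[1]
        warnings.warn(
            "both clusters have the same majority class; using the "
            "accuracy-maximizing one-to-one mapping",
            stacklevel=2,
        )
    else:
        pos_cluster = clusters[0] if majority[clusters[0]] else clusters[1]

    pred_pos = labels == pos_cluster
    return ConfusionMatrix(
        tp=int((pred_pos & is_pos).sum()),
        fp=int((pred_pos & ~is_pos).sum()),
        fn=int((~pred_pos & is_pos).sum()),
        tn=int((~pred_pos & ~is_pos).sum()),
    )


def proportion_ci(successes: int, trials: int, alpha: float = 0.05) -> tuple:
    """Clopper-Pearson exact binomial confidence interval."""
    if not 0 <= successes <= trials or trials < 1:
        raise ValueError(f"invalid counts {successes}/{trials}")
    lo, hi = proportion_confint(successes, trials, alpha=alpha, method="beta")
    # statsmodels returns NaN at the closed boundaries
    lo = 0.0 if successes == 0 else float(lo)
    hi = 1.0 if successes == trials else float(hi)
    return lo, hi


def lr_ci(c: ConfusionMatrix, which: str, alpha: float = 0.05) -> tuple:
    """Log-method confidence interval for a likelihood ratio.

    Uses ``SE(ln LR+) = sqrt(1/TP - 1/(TP+FN) + 1/FP - 1/(FP+TN))`` and the
    analogous expression with FN and TN for LR-; counts are the
    zero-cell-corrected ones from :meth:`ConfusionMatrix.corrected`.
    """
    if which not in ("pos", "neg"):
        raise ValueError("which must be 'pos' or 'neg'")
    tp, fp, fn, tn = c.corrected()
    z = norm.ppf(1 - alpha / 2)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    if which == "pos":
        lr = sens / (1 - spec)
        se = np.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
    else:
        lr = (1 - sens) / spec
        se = np.sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
    return float(np.exp(np.log(lr) - z * se)), float(np.exp(np.log(lr) + z * se))


@dataclass(frozen=True)
class DiagnosticReport:
    """Point estimates with 95% confidence limits for the seven measures."""

    estimates: dict
    confusion: ConfusionMatrix
    alpha: float = 0.05

    def __getitem__(self, measure: str) -> tuple:
        return self.estimates[measure]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "measure": m,
                "estimate": self.estimates[m][0],
                "lower95": self.estimates[m][1],
                "upper95": self.estimates[m][2],
            }
            for m in MEASURES
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().round(3).to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "alpha": self.alpha,
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
                "tn": self.confusion.tn,
            },
            "measures": {
                m: {
                    "estimate": self.estimates[m][0],
                    "lower95": self.estimates[m][1],
                    "upper95": self.estimates[m][2],
                }
                for m in MEASURES
            },
        }
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    def __str__(self) -> str:
        df = self.to_frame().copy()
        for c in ("estimate", "lower95", "upper95"):
            df[c] = df[c].map(lambda v: f"{v:.3f}")
        return df.to_string(index=False)


def _safe_ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def diagnostic_report(c: ConfusionMatrix, alpha: float = 0.05) -> DiagnosticReport:
    """Compute the seven diagnostic measures with 95% confidence intervals.

    A measure whose margin is empty (e.g. sensitivity with no diseased
    subjects) is reported as NaN with NaN limits rather than dropped.
    """
    n = c.total
    est = {}
    for m, num, den in (
        ("sensitivity", c.tp, c.tp + c.fn),
        ("specificity", c.tn, c.tn + c.fp),
        ("ppv", c.tp, c.tp + c.fp),
        ("npv", c.tn, c.tn + c.fn),
        ("accuracy", c.tp + c.tn, n),
    ):
        p = _safe_ratio(num, den)
        if np.isnan(p):
            warnings.warn(f"{m} is undefined (empty margin)", stacklevel=2)
            est[m] = (p, float("nan"), float("nan"))
        else:
            est[m] = (p, *proportion_ci(num, den, alpha))

    tp, fp, fn, tn = c.corrected()
    sens_c = tp / (tp + fn)
    spec_c = tn / (tn + fp)
    est["lr_pos"] = (sens_c / (1 - spec_c), *lr_ci(c, "pos", alpha))
    est["lr_neg"] = ((1 - sens_c) / spec_c, *lr_ci(c, "neg", alpha))
    out = {m: est[m] for m in MEASURES}
    return DiagnosticReport(out, c, alpha)
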