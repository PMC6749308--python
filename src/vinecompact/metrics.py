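"""Classification and regression performance metrics, and cross-validation plans.

Binary classification is summarised by sensitivity, specificity, precision,
F1 and intersection-over-union computed from a confusion table, plus the
area under the ROC curve.  Regression (compactness rating against the expert
panel mean) is summarised by the coefficient of determination R^2 and the
root mean squared error.  Cross-validation supports the three designs used
throughout the pipeline: stratified k-fold, leave-one-group-out (one fold
per dataset of origin) and leave-one-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import (
    KFold,
    LeaveOneGroupOut,
    LeaveOneOut,
    StratifiedKFold,
)

__all__ = [
    "ConfusionCounts",
    "CVPlan",
    "UndefinedMetricError",
    "auc",
    "binary_metrics",
    "make_cv_folds",
    "one_vs_rest_eval",
    "regression_metrics",
]


class UndefinedMetricError(ValueError):
    """A requested metric has a zero denominator for the given counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion table: true/false positives and negatives."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def binary_metrics(
    counts: ConfusionCounts,
    metrics: tuple[str, ...] = ("sensitivity", "specificity", "precision", "f1", "iou"),
) -> dict[str, float]:
    """Compute binary classification metrics from a confusion table.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    precision = TP/(TP+FP); F1 = 2*precision*sensitivity/(precision+sensitivity);
    IoU = TP/(TP+FP+FN).

    Raises
    ------
    UndefinedMetricError
        If a requested metric has a zero denominator.  Undefined values are
        never silently reported as 0.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denominators = {
        "sensitivity": tp + fn,
        "specificity": tn + fp,
        "precision": tp + fp,
        "f1": 2 * tp + fp + fn,
        "iou": tp + fp + fn,
    }
    out: dict[str, float] = {}
    for name in metrics:
        if name not in denominators:
            raise ValueError(f"unknown metric {name!r}")
        if denominators[name] == 0:
            raise UndefinedMetricError(
                f"metric {name!r} undefined: zero denominator for counts {counts}"
            )
    for name in metrics:
        if name == "sensitivity":
            out[name] = tp / (tp + fn)
        elif name == "specificity":
            out[name] = tn / (tn + fp)
        elif name == "precision":
            out[name] = tp / (tp + fp)
        elif name == "f1":
            # algebraically 2*P*S/(P+S) = 2TP/(2TP+FP+FN), defined whenever
            # the harmonic-mean denominator is nonzero
            out[name] = 2 * tp / (2 * tp + fp + fn)
        elif name == "iou":
            out[name] = tp / (tp + fp + fn)
    return out


def auc(scores, labels) -> float:
    """Area under the ROC curve with the rank (half-credit-for-ties) convention.

    Equivalent to the probability that a randomly chosen positive scores
    higher than a randomly chosen negative, with ties counting 1/2.

    Parameters
    ----------
    scores : array-like of float
        Decision scores, larger meaning more positive.
    labels : array-like of {0, 1} or bool
        True class per sample; both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks -> half credit for ties
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def regression_metrics(predicted, reference) -> dict[str, float]:
    """R^2 (about the reference mean) and RMSE of predictions.

    R^2 = 1 - SSE/SST is the coefficient of determination against the
    reference values themselves (it can be negative); ``pearson_r2``, the
    squared correlation, is also reported since the two conventions differ.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape or predicted.ndim != 1:
        raise ValueError("predicted and reference must be equal-length 1-d arrays")
    if predicted.size < 2:
        raise ValueError("need at least 2 samples")
    sse = float(np.sum((predicted - reference) ** 2))
    sst = float(np.sum((reference - reference.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedMetricError("R^2 undefined: reference variance is zero")
    rmse = float(np.sqrt(np.mean((predicted - reference) ** 2)))
    r = float(np.corrcoef(predicted, reference)[0, 1]) if predicted.std() > 0 else 0.0
    return {"r2": 1.0 - sse / sst, "rmse": rmse, "pearson_r2": r * r}


def one_vs_rest_eval(predicted_labels, truth_labels, positive_class) -> ConfusionCounts:
    """Confusion counts for one class against all others.

    Both label maps may be any matching-shape integer (or string) arrays;
    ``positive_class`` is the label value treated as positive.
    """
    predicted_labels = np.asarray(predicted_labels)
    truth_labels = np.asarray(truth_labels)
    if predicted_labels.shape != truth_labels.shape:
        raise ValueError("label maps must have the same shape")
    pred_pos = predicted_labels == positive_class
    true_pos = truth_labels == positive_class
    tp = int(np.sum(pred_pos & true_pos))
    fp = int(np.sum(pred_pos & ~true_pos))
    fn = int(np.sum(~pred_pos & true_pos))
    tn = int(np.sum(~pred_pos & ~true_pos))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def segmentation_report(predicted_labels, truth_labels, class_names):
    """Per-class one-vs-rest metric table (sensitivity, specificity, F1,
    AUC-free) for a segmentation against its truth map.

    Returns a list of dicts, one per class, with the five binary metrics;
    suitable for a DataFrame or CSV report.
    """
    rows = []
    for idx, name in enumerate(class_names):
        counts = one_vs_rest_eval(predicted_labels, truth_labels, idx)
        row = {"class": name, **binary_metrics(counts)}
        rows.append(row)
    return rows


@dataclass(frozen=True)
class CVPlan:
    """A cross-validation design.

    scheme : one of "stratified-k-fold", "leave-one-group-out", "leave-one-out"
    k : number of folds (stratified scheme only)
    seed : shuffling seed for the stratified scheme
    """

    scheme: str = "stratified-k-fold"
    k: int = 10
    seed: int = 0

    _SCHEMES = ("stratified-k-fold", "leave-one-group-out", "leave-one-out")

    def __post_init__(self) -> None:
        if self.scheme not in self._SCHEMES:
            raise ValueError(f"scheme must be one of {self._SCHEMES}")


def make_cv_folds(plan: CVPlan, n_samples: int, labels=None, groups=None):
    """Build (train_indices, test_indices) pairs for a CV plan.

    The test folds partition ``range(n_samples)`` exactly.  For the
    stratified scheme, per-class proportions are preserved within one
    sample per fold; when ``groups`` is also given, stratification is on
    the (class, group) pair so each test fold carries every dataset and
    class in equal proportion.  Leave-one-group-out yields one fold per
    unique group; leave-one-out yields ``n_samples`` singleton folds.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if plan.scheme == "leave-one-out":
        splitter = LeaveOneOut()
        split = splitter.split(np.zeros(n_samples))
    elif plan.scheme == "leave-one-group-out":
        if groups is None:
            raise ValueError("leave-one-group-out requires groups")
        groups = np.asarray(groups)
        if groups.shape[0] != n_samples:
            raise ValueError("groups length must equal n_samples")
        splitter = LeaveOneGroupOut()
        split = splitter.split(np.zeros(n_samples), groups=groups)
    else:
        if plan.k > n_samples:
            raise ValueError(f"k={plan.k} exceeds n_samples={n_samples}")
        if labels is None:
            splitter = KFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
            split = splitter.split(np.zeros(n_samples))
        else:
            labels = np.asarray(labels)
            if groups is not None:
                groups = np.asarray(groups)
                strata = np.array(
                    [f"{g}||{y}" for g, y in zip(groups, labels)], dtype=object
                )
            else:
                strata = labels
            splitter = StratifiedKFold(
                n_splits=plan.k, shuffle=True, random_state=plan.seed
            )
            split = splitter.split(np.zeros(n_samples), strata)
    return [(np.sort(tr), np.sort(te)) for tr, te in split]
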