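"""Metrics, curves, validation protocols and composition summaries.

Threshold metrics follow the standard confusion-count definitions

    Sen = tp/(tp+fn)   Spe = tn/(tn+fp)   Acc = (tp+tn)/n   Pre = tp/(tp+fp)
    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))

with zero-denominator cases surfaced as ``None`` (undefined), never as 0.
Two accuracy definitions co-exist and are named distinctly: *pooled*
accuracy (tp+tn)/n and *balanced overall* accuracy, the arithmetic mean of
per-class recalls (the convention for unbalanced independent test sets).

Validation protocols:

* class-balanced stratified k-fold CV (each item tested exactly once);
* bootstrap balanced CV — repeatedly draw equal-sized class samples from the
  two class pools without replacement, run k-fold CV in each bootstrap set,
  and report mean +- standard error over sets;
* jackknife (leave-one-out) validation of the one-vs-one multi-class model;
* independent-set evaluation of a two-stage predictor.

ROC points are swept over all distinct score thresholds (prediction positive
iff score >= threshold) and AUC-ROC is the trapezoidal area, which equals the
tie-corrected Mann-Whitney concordance.  AUC-PR is the step-wise average
precision over the recall axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import kmer_frequencies
from .seqio import LabeledDataset
from .svm_core import (
    KernelConfig,
    MulticlassModel,
    decision_values,
    predict_binary,
    predict_multiclass,
    train_binary_svm,
    train_multiclass,
)

__all__ = [
    "BinaryConfusion",
    "MetricSet",
    "BootstrapCVConfig",
    "MultiClassReport",
    "compute_metrics",
    "balanced_overall_accuracy",
    "roc_points_and_auc",
    "pr_points_and_auc",
    "stratified_kfold_cv",
    "bootstrap_balanced_cv",
    "jackknife_multiclass",
    "independent_two_stage_eval",
    "composition_summary",
    "class_correlation",
]


@dataclass(frozen=True)
class BinaryConfusion:
    """Confusion counts for one binary evaluation."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "BinaryConfusion") -> "BinaryConfusion":
        return BinaryConfusion(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass
class MetricSet:
    """Threshold metrics plus optional curve areas; undefined ratios are None."""

    sen: float | None = None
    spe: float | None = None
    acc: float | None = None
    pre: float | None = None
    mcc: float | None = None
    auc_roc: float | None = None
    auc_pr: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sen": self.sen,
            "spe": self.spe,
            "acc": self.acc,
            "pre": self.pre,
            "mcc": self.mcc,
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
        }


@dataclass(frozen=True)
class BootstrapCVConfig:
    """Protocol parameters for bootstrap balanced cross-validation."""

    n_bootstrap: int = 100
    per_class_n: int = 120
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1 or self.per_class_n < 1:
            raise ValueError("n_bootstrap and per_class_n must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class MultiClassReport:
    """m x m confusion (rows = true class) plus per-class one-vs-rest metrics."""

    confusion: pd.DataFrame
    per_class: dict[str, MetricSet] = field(default_factory=dict)

    @property
    def classes(self) -> list[str]:
        return list(self.confusion.index)

    @property
    def overall_accuracy(self) -> float:
        return float(np.diag(self.confusion.to_numpy()).sum() / self.confusion.to_numpy().sum())


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(c: BinaryConfusion) -> MetricSet:
    """Threshold metrics from confusion counts; zero denominators yield None."""
    mcc: float | None
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    else:
        mcc = None
    return MetricSet(
        sen=_ratio(c.tp, c.tp + c.fn),
        spe=_ratio(c.tn, c.tn + c.fp),
        acc=_ratio(c.tp + c.tn, c.total),
        pre=_ratio(c.tp, c.tp + c.fp),
        mcc=mcc,
    )


def balanced_overall_accuracy(recalls: Sequence[float]) -> float:
    """Arithmetic mean of per-class recall fractions."""
    recalls = list(recalls)
    if not recalls:
        raise ValueError("at least one recall value is required")
    if any(not 0 <= r <= 1 for r in recalls):
        raise ValueError("recalls must lie in [0, 1]")
    return float(np.mean(recalls))


def _check_scores(scores: Sequence[float], labels: Sequence[int | bool]):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return scores, labels


def roc_points_and_auc(
    scores: Sequence[float], labels: Sequence[int | bool]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (fpr, tpr) over all distinct thresholds, plus trapezoid AUC.

    Prediction is positive iff score >= threshold; (0,0) and (1,1) are always
    included.  The area equals the tie-corrected concordance statistic.
    """
    scores, labels = _check_scores(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:   # all items tied at this threshold
            tp += int(l[j])
            fp += int(not l[j])
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def pr_points_and_auc(
    scores: Sequence[float], labels: Sequence[int | bool]
) -> tuple[list[tuple[float, float]], float]:
    """Precision-recall points per threshold plus step-wise average precision.

    AUC-PR = sum over thresholds of (recall increment) * precision, the
    average-precision form of the integral of precision over recall.
    """
    scores, labels = _check_scores(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("PR curve requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    points: list[tuple[float, float]] = []
    tp = fp = 0
    auc = 0.0
    prev_recall = 0.0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            tp += int(l[j])
            fp += int(not l[j])
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        points.append((recall, precision))
        auc += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return points, float(auc)


@dataclass
class CVResult:
    """Output of one stratified k-fold CV run."""

    fold_confusions: list[BinaryConfusion]
    pooled: MetricSet
    pooled_confusion: BinaryConfusion
    fold_metrics: list[MetricSet]
    scores: np.ndarray          # held-out decision values, dataset order
    predictions: np.ndarray     # held-out labels, dataset order


def stratified_kfold_cv(
    X: np.ndarray,
    y: Sequence[str],
    config: KernelConfig = KernelConfig(),
    n_folds: int = 5,
    seed: int = 0,
    *,
    pos_label: str | None = None,
) -> CVResult:
    """Class-balanced k-fold CV of the binary SVM; each item tested once.

    Pooled metrics come from the summed confusion and the pooled held-out
    decision scores (for the curve areas); per-fold metrics are also kept.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, dtype=object)
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"binary CV needs exactly 2 classes, got {classes}")
    if pos_label is None:
        pos_label = classes[1]
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < n_folds:
        raise ValueError(f"every class must have >= {n_folds} members, got {counts}")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    preds = np.empty(len(y), dtype=object)
    fold_confusions: list[BinaryConfusion] = []
    for train_idx, test_idx in skf.split(X, y.astype(str)):
        model = train_binary_svm(
            X[train_idx], y[train_idx], config, pos_label=pos_label, calibrate=False
        )
        d = decision_values(model, X[test_idx])
        scores[test_idx] = d
        fold_pred = np.where(d >= 0, model.pos_label, model.neg_label)
        preds[test_idx] = fold_pred
        truth_pos = y[test_idx] == pos_label
        pred_pos = fold_pred == pos_label
        fold_confusions.append(
            BinaryConfusion(
                tp=int((truth_pos & pred_pos).sum()),
                tn=int((~truth_pos & ~pred_pos).sum()),
                fp=int((~truth_pos & pred_pos).sum()),
                fn=int((truth_pos & ~pred_pos).sum()),
            )
        )
    pooled_confusion = fold_confusions[0]
    for c in fold_confusions[1:]:
        pooled_confusion = pooled_confusion + c
    pooled = compute_metrics(pooled_confusion)
    is_pos = y == pos_label
    _, pooled.auc_roc = roc_points_and_auc(scores, is_pos)
    _, pooled.auc_pr = pr_points_and_auc(scores, is_pos)
    return CVResult(
        fold_confusions=fold_confusions,
        pooled=pooled,
        pooled_confusion=pooled_confusion,
        fold_metrics=[compute_metrics(c) for c in fold_confusions],
        scores=scores,
        predictions=preds,
    )


def bootstrap_balanced_cv(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    config: BootstrapCVConfig = BootstrapCVConfig(),
    kernel: KernelConfig = KernelConfig(),
    *,
    pos_label: str = "resistant",
    neg_label: str = "non-resistant",
) -> pd.DataFrame:
    """Balanced bootstrap CV over class pools; mean +- SE of pooled metrics.

    For each bootstrap set, ``per_class_n`` items are drawn from each pool
    without replacement (seeded), k-fold CV is run, and the set's pooled
    metrics collected; the report holds the mean and the standard error over
    sets for every metric.  A pure function of (pools, config, seeds).
    """
    X_pos = np.asarray(X_pos, float)
    X_neg = np.asarray(X_neg, float)
    n = config.per_class_n
    if len(X_pos) < n or len(X_neg) < n:
        raise ValueError(
            f"pools of {len(X_pos)} and {len(X_neg)} cannot supply {n} per class"
        )
    rng = np.random.default_rng(config.seed)
    labels = np.array([pos_label] * n + [neg_label] * n, dtype=object)
    per_set: list[dict[str, float | None]] = []
    for b in range(config.n_bootstrap):
        pos_idx = rng.choice(len(X_pos), size=n, replace=False)
        neg_idx = rng.choice(len(X_neg), size=n, replace=False)
        Xb = np.vstack([X_pos[pos_idx], X_neg[neg_idx]])
        fold_seed = int(rng.integers(0, 2**31 - 1))
        result = stratified_kfold_cv(
            Xb, labels, kernel, config.n_folds, fold_seed, pos_label=pos_label
        )
        per_set.append(result.pooled.as_dict())
    table = pd.DataFrame(per_set, dtype=float)
    out = pd.DataFrame(
        {
            "mean": table.mean(),
            "se": table.std(ddof=1) / math.sqrt(len(table)) if len(table) > 1 else np.nan,
        }
    )
    out.index.name = "metric"
    return out


def _one_vs_rest_confusion(
    y_true: np.ndarray, y_pred: np.ndarray, cls: str
) -> BinaryConfusion:
    truth = y_true == cls
    pred = y_pred == cls
    return BinaryConfusion(
        tp=int((truth & pred).sum()),
        tn=int((~truth & ~pred).sum()),
        fp=int((~truth & pred).sum()),
        fn=int((truth & ~pred).sum()),
    )


def jackknife_multiclass(
    X: np.ndarray,
    y: Sequence[str],
    config: KernelConfig = KernelConfig(),
) -> MultiClassReport:
    """Leave-one-out validation of the one-vs-one multi-class SVM.

    Every observation is predicted once by a model trained on all others;
    n fits for n observations.  Classes of size 1 are rejected (their
    singleton round would train without the class).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, dtype=object)
    classes = sorted(set(y))
    singletons = [c for c in classes if (y == c).sum() < 2]
    if singletons:
        raise ValueError(f"classes with a single member cannot be jackknifed: {singletons}")
    preds = np.empty(len(y), dtype=object)
    idx = np.arange(len(y))
    for i in idx:
        mask = idx != i
        model = train_multiclass(X[mask], y[mask], config, calibrate=False)
        preds[i] = predict_multiclass(model, X[i][None, :])[0]
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y, preds):
        confusion.loc[t, p] += 1
    per_class = {
        c: compute_metrics(_one_vs_rest_confusion(y, preds, c)) for c in classes
    }
    return MultiClassReport(confusion=confusion, per_class=per_class)


def independent_two_stage_eval(
    model,                      # TwoStageModel; imported lazily to avoid a cycle
    test: LabeledDataset,
) -> tuple[pd.DataFrame, float, dict[str, float]]:
    """Evaluate a two-stage predictor on an 8-class independent set.

    Returns the 8x8 confusion (rows = true labels), the balanced overall
    accuracy — the mean of the pooled resistant recall (resistant sequences
    assigned to their *own* class) and the non-resistant recall — and the
    per-class recalls.
    """
    from .two_stage import NON_RESISTANT, RESISTANT_CLASSES, predict_two_stage

    valid = set(RESISTANT_CLASSES) | {NON_RESISTANT}
    unknown = sorted(set(test.labels) - valid)
    if unknown:
        raise ValueError(f"labels outside the 8-class set: {unknown}")
    rows = predict_two_stage(model, test.records)
    all_classes = list(RESISTANT_CLASSES) + [NON_RESISTANT]
    confusion = pd.DataFrame(0, index=all_classes, columns=all_classes, dtype=int)
    for row, truth in zip(rows, test.labels):
        if row.failed:
            continue
        confusion.loc[truth, row.predicted_class] += 1
    diag = {c: int(confusion.loc[c, c]) for c in all_classes}
    res_total = sum(int(confusion.loc[c].sum()) for c in RESISTANT_CLASSES)
    res_correct = sum(diag[c] for c in RESISTANT_CLASSES)
    nonres_total = int(confusion.loc[NON_RESISTANT].sum())
    per_class = {
        c: diag[c] / int(confusion.loc[c].sum())
        for c in all_classes
        if int(confusion.loc[c].sum()) > 0
    }
    recalls = []
    if res_total > 0:
        recalls.append(res_correct / res_total)
    if nonres_total > 0:
        recalls.append(diag[NON_RESISTANT] / nonres_total)
    return confusion, balanced_overall_accuracy(recalls), per_class


def composition_summary(dataset: LabeledDataset, k: int) -> pd.DataFrame:
    """Per-class mean k-mer composition (classes x 4^k), for heat maps."""
    from .features import enumerate_kmers

    classes = sorted(set(dataset.labels))
    rows = {}
    for cls in classes:
        records = dataset.subset(cls)
        if not records:
            raise ValueError(f"class {cls!r} is empty")
        rows[cls] = np.mean(
            [kmer_frequencies(r.residues, k) for r in records], axis=0
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=enumerate_kmers(k))


def class_correlation(summary: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between class mean-composition vectors.

    Symmetric with unit diagonal; classes whose composition vector has zero
    variance get NaN correlations (undefined, flagged via a warning).
    """
    values = summary.to_numpy(float)
    sds = values.std(axis=1)
    flat = np.flatnonzero(sds == 0)
    if flat.size:
        import warnings

        warnings.warn(
            f"zero-variance composition for classes {list(summary.index[flat])}; "
            "their correlations are undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    n = len(summary)
    corr = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if sds[i] == 0 or sds[j] == 0:
                continue
            xi = values[i] - values[i].mean()
            xj = values[j] - values[j].mean()
            corr[i, j] = float(xi @ xj / np.sqrt((xi @ xi) * (xj @ xj)))
    np.fill_diagonal(corr, np.where(sds == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=summary.index, columns=summary.index)
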