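"""Classification metrics, cross-validation and repeated-holdout summaries.

Metrics follow the standard confusion-count definitions for a binary
toxicity endpoint (positive = hepatotoxic):

    Q   = (TP + TN) / (TP + TN + FP + FN)          accuracy
    SE  = TP / (TP + FN)                           sensitivity / recall
    SP  = TN / (TN + FP)                           specificity
    PRE = TP / (TP + FP)                           precision
    F1  = TP / (TP + (FP + FN) / 2)
    BA  = (SE + SP) / 2                            balanced accuracy
    AUC = P(score(pos) > score(neg)), ties 1/2     rank/trapezoid equivalence

All metrics are kept as fractions in [0, 1]; report layers render them as
percentages. A 0/0 metric is reported as NaN (an explicit undefined
marker), never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import DegenerateLabels, SchemaError, StratificationError

#: Explicit marker for a 0/0 metric.
UNDEFINED = float("nan")

METRIC_ORDER = ("accuracy", "auc", "f1", "sensitivity", "specificity", "precision", "balanced_accuracy")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """All headline metrics of one evaluation, as fractions in [0, 1]."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    balanced_accuracy: float
    auc: float = UNDEFINED
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_ORDER}

    def as_percent_dict(self, ndigits: int = 2) -> dict[str, float]:
        return {
            k: (round(100 * v, ndigits) if not math.isnan(v) else UNDEFINED)
            for k, v in self.as_dict().items()
        }


@dataclass
class CVReport:
    """Per-fold metrics of a stratified k-fold run plus mean +/- SD."""

    k: int
    seed: int
    fold_reports: list[MetricsReport]
    fold_assignment: dict[int, int]  # sample index -> validation fold
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.mean:
            table = {m: [getattr(r, m) for r in self.fold_reports] for m in METRIC_ORDER}
            self.mean = {m: float(np.nanmean(v)) for m, v in table.items()}
            self.sd = {m: float(np.nanstd(v, ddof=1)) for m, v in table.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.fold_reports]
        df = pd.DataFrame(rows, index=[f"fold_{i}" for i in range(self.k)])
        df.loc["mean"] = self.mean
        df.loc["sd"] = self.sd
        return df


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN for binary labels (positive class = 1)."""
    yt = np.asarray(y_true, dtype=int).ravel()
    yp = np.asarray(y_pred, dtype=int).ravel()
    if yt.shape != yp.shape:
        raise SchemaError("y_true and y_pred lengths differ")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("labels must be 0/1")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else UNDEFINED


def compute_metrics(
    c: ConfusionCounts,
    scores: Sequence[float] | None = None,
    y_true: Sequence[int] | None = None,
) -> MetricsReport:
    """Metrics report from counts; AUC filled in when scores are supplied.

    Any 0/0 ratio (e.g. sensitivity with no positives) is reported as NaN.
    """
    if c.total <= 0:
        raise ValueError("confusion counts must cover at least one sample")
    se = _ratio(c.tp, c.tp + c.fn)
    sp = _ratio(c.tn, c.tn + c.fp)
    ba = (se + sp) / 2  # NaN-propagating by design
    auc = UNDEFINED
    if scores is not None:
        if y_true is None:
            raise ValueError("y_true is required alongside scores")
        try:
            auc = roc_auc(y_true, scores)
        except DegenerateLabels:
            auc = UNDEFINED
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=se,
        specificity=sp,
        precision=_ratio(c.tp, c.tp + c.fp),
        f1=_f1(c),
        balanced_accuracy=ba,
        auc=auc,
        counts=c,
    )


def _f1(c: ConfusionCounts) -> float:
    den = c.tp + 0.5 * (c.fp + c.fn)
    return c.tp / den if den > 0 else UNDEFINED


def roc_auc(y_true, scores) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties 1/2.

    Raises
    ------
    DegenerateLabels
        If only one class is present.
    """
    yt = np.asarray(y_true, dtype=int).ravel()
    if len(np.unique(yt)) < 2:
        raise DegenerateLabels("AUC needs both classes present")
    return float(roc_auc_score(yt, np.asarray(scores, dtype=float).ravel()))


def roc_points(y_true, scores) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for CSV export/plotting."""
    fpr, tpr, thr = roc_curve(np.asarray(y_true, int), np.asarray(scores, float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def evaluate_predictions(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Convenience: counts + metrics + AUC from probabilities."""
    y_pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return compute_metrics(confusion_counts(y_true, y_pred), scores=scores, y_true=y_true)


def kfold_cross_validate(
    pipeline_factory: Callable[[int], object],
    X,
    y,
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV re-running the whole pipeline inside each fold.

    ``pipeline_factory(seed)`` must return a fresh object with
    ``fit(X_train, y_train)`` and ``predict_proba(X) -> P(class 1)``; any
    scaling or feature selection it performs is therefore refitted on each
    fold's training rows only.

    Raises
    ------
    StratificationError
        If either class has fewer than ``k`` members.
    """
    ya = np.asarray(y, dtype=int).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    for cls in (0, 1):
        if int(np.sum(ya == cls)) < k:
            raise StratificationError(f"class {cls} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    Xa = X.values if hasattr(X, "values") and not isinstance(X, np.ndarray) else np.asarray(X)
    reports: list[MetricsReport] = []
    assignment: dict[int, int] = {}
    for fold, (tr, va) in enumerate(skf.split(Xa, ya)):
        for i in va:
            assignment[int(i)] = fold
        pipe = pipeline_factory(seed)
        pipe.fit(_rows(X, tr), ya[tr])
        scores = np.asarray(pipe.predict_proba(_rows(X, va)), dtype=float)
        if scores.ndim == 2:  # sklearn-style (n, 2) output
            scores = scores[:, 1]
        reports.append(evaluate_predictions(ya[va], scores))
    return CVReport(k=k, seed=seed, fold_reports=reports, fold_assignment=assignment)


def _rows(X, idx):
    if hasattr(X, "take_rows"):
        return X.take_rows(idx)
    return np.asarray(X)[idx]


def repeated_holdout_summary(
    pipeline_factory: Callable[[int], object],
    X,
    y,
    n_repeats: int = 5,
    seeds: Sequence[int] | None = None,
    test_fraction: float = 0.2,
) -> tuple[dict[str, float], dict[str, float], list[MetricsReport]]:
    """Mean +/- SD metrics over fresh stratified holdouts (one per seed).

    Each repeat redraws the 80/20 split and reseeds the pipeline, so both
    sources of variation contribute to the spread.
    """
    if seeds is None:
        seeds = list(range(n_repeats))
    if len(seeds) < 2:
        raise ValueError("need at least 2 repeats")
    ya = np.asarray(y, dtype=int).ravel()
    reports = []
    for seed in seeds:
        tr, va = train_test_split(
            np.arange(len(ya)), test_size=test_fraction, random_state=seed, stratify=ya
        )
        pipe = pipeline_factory(seed)
        pipe.fit(_rows(X, tr), ya[tr])
        scores = np.asarray(pipe.predict_proba(_rows(X, va)), dtype=float)
        if scores.ndim == 2:
            scores = scores[:, 1]
        reports.append(evaluate_predictions(ya[va], scores))
    table = {m: [getattr(r, m) for r in reports] for m in METRIC_ORDER}
    mean = {m: float(np.nanmean(v)) for m, v in table.items()}
    sd = {m: float(np.nanstd(v, ddof=1)) for m, v in table.items()}
    return mean, sd, reports


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Degenerate inputs are resolved explicitly: zero within-group variance
    with equal means gives (0, 1); zero within-group variance with unequal
    means gives (inf, 0).
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ssb = sum(len(a) * (a.mean() - grand.mean()) ** 2 for a in arrays)
    if ssw == 0:
        return (0.0, 1.0) if ssb == 0 else (float("inf"), 0.0)
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def metrics_frame(named_reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Model-by-metric table in the conventional report column order."""
    return pd.DataFrame({name: r.as_dict() for name, r in named_reports.items()}).T[list(METRIC_ORDER)]
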