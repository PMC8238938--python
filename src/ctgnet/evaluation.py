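"""Evaluation protocol: confusion counts, precision/recall/F1, ROC-AUC by
threshold sweep, tenfold cross-validation with normal-resampling, multi-seed
repetition and model comparison tests.

The positive class is the abnormal delivery throughout. Precision, recall and
F1 follow the usual definitions (F1 the harmonic mean of the first two), with
0/0 defined as 0. The ROC is swept over the distinct observed scores and the
AUC computed by the trapezoid rule, which is equivalent to Mann–Whitney pair
counting with half credit for ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "ROCCurve",
    "CVResult",
    "ComparisonResult",
    "confusion",
    "f1_score",
    "roc_auc",
    "tenfold_cv",
    "repeat_with_seeds",
    "compare_models",
    "format_mean_sd",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class CVResult:
    fold_metrics: list[Metrics]
    fold_roc: list[ROCCurve]
    test_fold_ids: list[list]
    f1_mean: float
    f1_sd: float
    auc_mean: float
    auc_sd: float


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Tally confusion counts; 1/'abnormal' is the positive class."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")

    def _pos(a):
        return (a == 1) | (a == "abnormal") | (a == True)  # noqa: E712

    yp, pp = _pos(y), _pos(p)
    return ConfusionCounts(
        tp=int(np.sum(yp & pp)),
        fp=int(np.sum(~yp & pp)),
        fn=int(np.sum(yp & ~pp)),
        tn=int(np.sum(~yp & ~pp)),
    )


def f1_score(counts: ConfusionCounts) -> Metrics:
    """Precision, recall and their harmonic mean; 0/0 ratios are defined as 0."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    denom = precision + recall
    f1 = 2.0 * precision * recall / denom if denom else 0.0
    return Metrics(precision=precision, recall=recall, f1=f1)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC by sweeping thresholds over the distinct scores; trapezoidal AUC.

    Equals the fraction of (abnormal, normal) score pairs correctly ordered,
    with ties counted half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = (y == 1) | (y == "abnormal")
    n_pos = int(pos.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes in the labels")
    thresholds = np.unique(s)[::-1]
    tpr = np.empty(len(thresholds) + 1)
    fpr = np.empty(len(thresholds) + 1)
    tpr[0] = fpr[0] = 0.0
    for i, th in enumerate(thresholds, start=1):
        pred = s >= th
        tpr[i] = np.sum(pred & pos) / n_pos
        fpr[i] = np.sum(pred & ~pos) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


class ScoringModel(Protocol):
    def fit(self, X, y) -> None: ...

    def score(self, X) -> np.ndarray: ...


def tenfold_cv(
    dataset_builder: Callable[[int, np.random.Generator], tuple],
    model_factory: Callable[[int], ScoringModel],
    n_folds: int = 10,
    seed: int = 0,
    decision_threshold: float = 0.5,
) -> CVResult:
    """Tenfold cross-validation with per-repetition normal resampling.

    ``dataset_builder(rep, rng)`` returns a balanced ``(X, y, ids)`` triple
    for repetition ``rep``; the abnormal half must be identical across
    repetitions (it is partitioned once into ``n_folds`` disjoint test folds,
    each serving as the test fold exactly once), while the normal half may be
    a fresh subsample each time, split 9:1 into train and test.

    ``model_factory(seed)`` returns an object with ``fit(X, y)`` and
    ``score(X)`` (abnormality scores; labels at ``decision_threshold``), and
    optionally ``predict(X)`` for hard labels.
    """
    rng = np.random.default_rng(seed)
    X0, y0, ids0 = dataset_builder(0, rng)
    ab_ids = [i for i, lab in zip(ids0, np.asarray(y0)) if lab == 1]
    if len(ab_ids) < n_folds:
        raise ValueError(f"abnormal class of size {len(ab_ids)} cannot fill {n_folds} folds")
    perm = rng.permutation(len(ab_ids))
    folds = [sorted(perm[f::n_folds]) for f in range(n_folds)]
    fold_ids = [{ab_ids[i] for i in f} for f in folds]

    fold_metrics: list[Metrics] = []
    fold_roc: list[ROCCurve] = []
    test_fold_ids: list[list] = []
    for rep in range(n_folds):
        X, y, ids = dataset_builder(rep, rng) if rep else (X0, y0, ids0)
        y = np.asarray(y)
        ids = list(ids)
        is_ab = y == 1
        test_mask = np.zeros(len(y), dtype=bool)
        for i, (lab, rid) in enumerate(zip(y, ids)):
            if lab == 1 and rid in fold_ids[rep]:
                test_mask[i] = True
        normal_idx = np.nonzero(~is_ab)[0]
        n_test_norm = int(test_mask.sum())
        test_norm = rng.choice(normal_idx, n_test_norm, replace=False)
        test_mask[test_norm] = True

        model = model_factory(seed * 1000 + rep)
        model.fit(X[~test_mask], y[~test_mask])
        scores = np.asarray(model.score(X[test_mask]), dtype=float)
        if hasattr(model, "predict"):
            preds = np.asarray(model.predict(X[test_mask]))
        else:
            preds = (scores >= decision_threshold).astype(int)
        fold_metrics.append(f1_score(confusion(y[test_mask], preds)))
        fold_roc.append(roc_auc(scores, y[test_mask]))
        test_fold_ids.append([ids[i] for i in np.nonzero(test_mask)[0] if y[i] == 1])

    f1s = np.array([m.f1 for m in fold_metrics])
    aucs = np.array([r.auc for r in fold_roc])
    return CVResult(
        fold_metrics=fold_metrics,
        fold_roc=fold_roc,
        test_fold_ids=test_fold_ids,
        f1_mean=float(f1s.mean()),
        f1_sd=float(f1s.std(ddof=1)),
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)),
    )


def repeat_with_seeds(
    protocol: Callable[[int], Mapping[str, float]], seeds: Sequence[int]
) -> list[dict[str, float]]:
    """Run a full evaluation protocol once per seed; returns per-seed summaries."""
    if len(seeds) < 2:
        raise ValueError("need at least two seeds for a reproducibility sweep")
    return [dict(protocol(int(s))) for s in seeds]


@dataclass(frozen=True)
class ComparisonResult:
    t: float
    p: float
    df: int
    t_paired: float | None = None
    p_paired: float | None = None
    df_paired: int | None = None


def compare_models(metrics_a: Sequence[float], metrics_b: Sequence[float]) -> ComparisonResult:
    """Two-sample Student's t-test on per-seed metrics (paired variant when
    the lists align)."""
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each metric list must contain at least two values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both samples have zero variance; the t-test is undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    t_p = p_p = df_p = None
    if len(a) == len(b):
        diffs = a - b
        if diffs.std(ddof=1) > 0:
            tp_, pp_ = stats.ttest_rel(a, b)
            t_p, p_p, df_p = float(tp_), float(pp_), len(a) - 1
        elif np.allclose(diffs, 0):
            t_p, p_p, df_p = 0.0, 1.0, len(a) - 1
    return ComparisonResult(t=float(t), p=float(p), df=df, t_paired=t_p, p_paired=p_p, df_paired=df_p)


def format_mean_sd(values: Sequence[float], digits: int = 2) -> str:
    v = np.asarray(values, dtype=float)
    return f"{v.mean():.{digits}f} ± {v.std(ddof=1):.{digits}f}"
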