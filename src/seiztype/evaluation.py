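"""Class rebalancing, cross-validation, classification metrics and ANOVA
feature screening.

Metrics are computed one-vs-rest per class from the K x K confusion
matrix — sensitivity SN = TP/(TP+FN), specificity SP = TN/(TN+FP),
precision PR = TP/(TP+FP), accuracy Ac = (TP+TN)/n, F1 = 2TP/(2TP+FP+FN)
and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

— then macro-averaged (unweighted mean over classes). MCC is binary by
definition; the multiclass value reported by default is the macro average
of the one-vs-rest binary MCCs, with the Gorodkin R_K generalization
available as an option. Cells with a zero denominator score 0 and are
flagged.

Class imbalance is handled by random undersampling (RUS): every class is
downsampled without replacement to the minority-class count, e.g.
83/114/282 onset channels become 83 per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .exceptions import InvalidArgumentError
from .models import SeizureSVC

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "FoldPlan",
    "random_undersample",
    "stratified_kfold",
    "confusion",
    "metrics",
    "cross_validated_report",
    "anova_oneway",
]


@dataclass
class ConfusionCounts:
    """K x K confusion matrix with per-class one-vs-rest counts."""

    labels: list
    matrix: np.ndarray  # rows = true, cols = predicted
    per_class: dict = field(default_factory=dict)  # label -> dict(TP, TN, FP, FN)

    @property
    def n(self) -> int:
        return int(self.matrix.sum())


@dataclass
class MetricsReport:
    """Per-class and macro metrics (SN, SP, PR, Ac, F1, MCC)."""

    per_class: pd.DataFrame  # index = labels, columns = metric names
    macro: dict  # metric name -> unweighted mean over classes
    counts: ConfusionCounts
    flags: list = field(default_factory=list)  # zero-denominator notes
    mcc_multiclass_rk: float | None = None  # Gorodkin R_K, if requested


@dataclass
class FoldPlan:
    """Stratified k-fold assignment of row indices."""

    folds: list  # list of index arrays
    k: int
    seed: int | None

    def splits(self):
        """Yield (train_indices, test_indices) per fold."""
        all_idx = np.concatenate(self.folds)
        for fold in self.folds:
            mask = np.isin(all_idx, fold)
            yield np.sort(all_idx[~mask]), np.sort(fold)


def random_undersample(
    table: pd.DataFrame, seed: int | None = None, label_col: str = "label"
) -> pd.DataFrame:
    """Downsample every class, without replacement, to the minority count."""
    counts = table[label_col].value_counts()
    if counts.size < 2:
        raise InvalidArgumentError("need at least two classes to rebalance")
    if (counts == 0).any():
        raise InvalidArgumentError("empty class")
    target = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = []
    for label in sorted(counts.index):
        rows = table.index[table[label_col] == label].to_numpy()
        if rows.size > target:
            rows = np.sort(rng.choice(rows, size=target, replace=False))
        keep.append(rows)
    return table.loc[np.concatenate(keep)].copy()


def stratified_kfold(labels, k: int = 10, seed: int | None = None) -> FoldPlan:
    """Stratified fold plan: per-class counts across folds differ by <= 1."""
    labels = np.asarray(labels)
    if k < 2:
        raise InvalidArgumentError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise InvalidArgumentError(
            f"classes with fewer than k={k} samples: {small.tolist()}"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [test for _, test in splitter.split(np.zeros(labels.size), labels)]
    return FoldPlan(folds=folds, k=k, seed=seed)


def confusion(y_true, y_pred, labels=None) -> ConfusionCounts:
    """Confusion matrix plus per-class one-vs-rest TP/TN/FP/FN."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise InvalidArgumentError("label vectors differ in length")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    matrix = _sk_confusion(y_true, y_pred, labels=labels)
    n = matrix.sum()
    per_class = {}
    for i, lab in enumerate(labels):
        tp = matrix[i, i]
        fn = matrix[i, :].sum() - tp
        fp = matrix[:, i].sum() - tp
        tn = n - tp - fn - fp
        per_class[lab] = {"TP": int(tp), "TN": int(tn), "FP": int(fp), "FN": int(fn)}
    return ConfusionCounts(labels=list(labels), matrix=matrix, per_class=per_class)


def _binary_metrics(tp, tn, fp, fn, flags, label):
    def ratio(num, den, name):
        if den == 0:
            flags.append(f"{label}:{name}:zero-denominator")
            return 0.0
        return num / den

    sn = ratio(tp, tp + fn, "SN")
    sp = ratio(tn, tn + fp, "SP")
    pr = ratio(tp, tp + fp, "PR")
    ac = ratio(tp + tn, tp + tn + fp + fn, "Ac")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "F1")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        flags.append(f"{label}:MCC:zero-denominator")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(denom))
    return {"SN": sn, "SP": sp, "PR": pr, "Ac": ac, "F1": f1, "MCC": mcc}


def _gorodkin_rk(matrix: np.ndarray) -> float:
    """Multiclass MCC generalization (R_K statistic)."""
    c = matrix.astype(float)
    n = c.sum()
    correct = np.trace(c)
    t = c.sum(axis=1)  # true counts
    p = c.sum(axis=0)  # predicted counts
    cov_xy = correct * n - t @ p
    cov_xx = n**2 - p @ p
    cov_yy = n**2 - t @ t
    denom = np.sqrt(cov_xx * cov_yy)
    return float(cov_xy / denom) if denom > 0 else 0.0


def metrics(counts: ConfusionCounts, multiclass_mcc: str = "macro-ovr") -> MetricsReport:
    """Metric report from confusion counts.

    ``multiclass_mcc``: "macro-ovr" (default, mean of one-vs-rest binary
    MCCs) or "rk" to additionally report the Gorodkin R_K statistic.
    """
    if counts.n == 0:
        raise InvalidArgumentError("empty confusion matrix")
    flags: list[str] = []
    rows = {
        lab: _binary_metrics(
            c["TP"], c["TN"], c["FP"], c["FN"], flags, lab
        )
        for lab, c in counts.per_class.items()
    }
    per_class = pd.DataFrame(rows).T
    macro = per_class.mean(axis=0).to_dict()
    rk = _gorodkin_rk(counts.matrix) if multiclass_mcc == "rk" else None
    return MetricsReport(
        per_class=per_class, macro=macro, counts=counts, flags=flags,
        mcc_multiclass_rk=rk,
    )


def cross_validated_report(
    table: pd.DataFrame,
    C: float = 1.0,
    gamma: float = 1.0,
    k: int = 10,
    seed: int | None = None,
    feature_columns=None,
    label_col: str = "label",
) -> tuple[MetricsReport, list[float]]:
    """Stratified k-fold CV of a :class:`SeizureSVC` on a feature table.

    Per fold the model (including its standardization) is fit on the
    training rows only; held-out predictions are pooled over folds into a
    single confusion matrix. Returns the pooled report and the per-fold
    accuracies.
    """
    cols = list(feature_columns) if feature_columns is not None else [
        c for c in table.columns if c not in ("channel_id", label_col)
    ]
    X = table[cols].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    plan = stratified_kfold(y, k=k, seed=seed)
    pooled_true, pooled_pred, fold_acc = [], [], []
    for train_idx, test_idx in plan.splits():
        model = SeizureSVC(C=C, gamma=gamma).fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        pooled_true.append(y[test_idx])
        pooled_pred.append(pred)
        fold_acc.append(float(np.mean(pred == y[test_idx])))
    counts = confusion(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    return metrics(counts), fold_acc


def anova_oneway(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA of one feature column across class labels.

    Returns (F, p). Degenerate input (zero within- and between-group
    variance) raises :class:`InvalidArgumentError` rather than returning
    NaN.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise InvalidArgumentError("values and groups differ in length")
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2:
        raise InvalidArgumentError("need at least two groups")
    if any(s.size < 2 for s in samples):
        raise InvalidArgumentError("every group needs at least two values")
    if all(np.ptp(s) == 0 for s in samples) and np.ptp(values) == 0:
        raise InvalidArgumentError("degenerate: all values identical")
    with np.errstate(invalid="ignore"):
        f_stat, p_value = stats.f_oneway(*samples)
    return float(f_stat), float(p_value)
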