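"""Classification metrics and the selective-prediction evaluation protocol.

The centrepiece is the retention curve: predictions are sorted by an
uncertainty score, the top 10% most-uncertain are discarded step by step
(retained fraction 1.0, 0.9, …, 0.1), and the Matthews correlation
coefficient (MCC) of each retained subset is computed. A useful uncertainty
score concentrates errors at high uncertainty, so MCC rises as coverage
shrinks; a useless one gives a flat curve. The scalar summary MCC_AUC is the
trapezoidal area of MCC over the retained-fraction axis divided by the span,
i.e. a span-averaged MCC in [−1, 1] (a constant curve scores that constant).

MCC and balanced accuracy (BACC) are used because permeability datasets are
imbalanced (BBB+ outnumbers BBB− roughly 3:1 in the public benchmarks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .exceptions import (
    EmptyAfterFilter,
    LengthMismatch,
    MissingProbabilities,
    NonMonotoneEdges,
)
from .uncertainty import UncertaintyVector

#: retained fractions 1.0, 0.9, ..., 0.1 (10% steps)
DEFAULT_FRACTIONS = tuple(np.round(np.arange(1.0, 0.05, -0.1), 10))


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsRecord:
    mcc: float
    bacc: float
    recall: float
    precision: float
    fpr: float
    roc_auc: float | None = None
    prc_auc: float | None = None


@dataclass
class RetentionCurve:
    fractions: np.ndarray  # strictly decreasing
    mcc_at: np.ndarray
    mcc_auc: float


@dataclass
class BinSummary:
    edges: np.ndarray
    counts: dict  # {"tp": array, "tn": ..., "fp": ..., "fn": ...} per bin
    totals: np.ndarray
    percentages: dict  # same keys; per-bin percentages (0 where bin empty)


def _as_binary(a) -> np.ndarray:
    arr = np.asarray(a)
    if arr.dtype.kind in "US":
        arr = np.array([1 if str(v) == "positive" else 0 for v in arr])
    return arr.astype(int)


def confusion_counts(labels, hard_labels) -> ConfusionCounts:
    """2x2 tally; positive class = BBB+ (encoded 1)."""
    y = _as_binary(labels)
    yhat = _as_binary(hard_labels)
    if y.shape[0] != yhat.shape[0]:
        raise LengthMismatch(f"{y.shape[0]} vs {yhat.shape[0]}")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
    )


def mcc_from_counts(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 by convention when the denominator
    vanishes (single-class subsets at small retained fractions)."""
    num = c.tp * c.tn - c.fp * c.fn
    den = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if den == 0:
        return 0.0
    return num / float(np.sqrt(den))


def bacc_from_counts(c: ConfusionCounts) -> float:
    """Balanced accuracy = (sensitivity + specificity) / 2."""
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    return (sens + spec) / 2.0


def classification_metrics(
    counts: ConfusionCounts,
    labels=None,
    probabilities=None,
) -> MetricsRecord:
    """Threshold metrics from counts; ranking AUCs if probabilities given.

    fpr = FP/(TN+FP), recall = TP/(TP+FN), precision = TP/(TP+FP) (each 0
    on an empty denominator). ROC_AUC is trapezoidal; PRC_AUC is average
    precision. Passing only one of labels/probabilities is an error.
    """
    if (labels is None) != (probabilities is None):
        raise MissingProbabilities("ranking AUCs need both labels and probabilities")
    roc = prc = None
    if probabilities is not None:
        y = _as_binary(labels)
        p = np.asarray(probabilities, dtype=np.float64)
        roc = float(roc_auc_score(y, p))
        prc = float(average_precision_score(y, p))
    return MetricsRecord(
        mcc=mcc_from_counts(counts),
        bacc=bacc_from_counts(counts),
        recall=counts.tp / (counts.tp + counts.fn) if (counts.tp + counts.fn) else 0.0,
        precision=counts.tp / (counts.tp + counts.fp) if (counts.tp + counts.fp) else 0.0,
        fpr=counts.fp / (counts.tn + counts.fp) if (counts.tn + counts.fp) else 0.0,
        roc_auc=roc,
        prc_auc=prc,
    )


def _uvalues(uncertainty) -> np.ndarray:
    if isinstance(uncertainty, UncertaintyVector):
        return uncertainty.values
    return np.asarray(uncertainty, dtype=np.float64)


def retention_curve(
    labels,
    hard_labels,
    uncertainty,
    fractions=DEFAULT_FRACTIONS,
) -> RetentionCurve:
    """MCC of the retained subset as high-uncertainty predictions are dropped.

    For each fraction f the ceil(f*n) lowest-uncertainty predictions are
    kept (ties broken by original order, stable). MCC_AUC is the trapezoid
    of MCC over f, divided by the span of f, so a constant curve scores that
    constant.

    Subset MCC convention: an error-free retained subset scores 1.0 even
    when it contains a single class (discarding uncertain predictions often
    leaves only confident members of the majority class; a perfectly
    predicted subset is the protocol's best outcome, not an undefined one).
    Any other subset with a vanishing MCC denominator scores 0.
    """
    y = _as_binary(labels)
    yhat = _as_binary(hard_labels)
    u = _uvalues(uncertainty)
    if not (y.shape[0] == yhat.shape[0] == u.shape[0]):
        raise LengthMismatch("labels / predictions / uncertainty misaligned")
    n = y.shape[0]
    fr = np.asarray(sorted(set(float(f) for f in fractions), reverse=True))
    order = np.argsort(u, kind="stable")  # lowest uncertainty first
    mcc_at = []
    for f in fr:
        k = int(np.ceil(f * n))
        if k == 0:
            raise EmptyAfterFilter(f"fraction {f} keeps zero of {n} predictions")
        keep = order[:k]
        c = confusion_counts(y[keep], yhat[keep])
        mcc_at.append(1.0 if (c.fp + c.fn) == 0 else mcc_from_counts(c))
    mcc_at = np.asarray(mcc_at)
    if fr.size == 1:
        auc = float(mcc_at[0])
    else:
        span = fr.max() - fr.min()
        auc = float(np.trapezoid(mcc_at[::-1], x=fr[::-1]) / span)
    return RetentionCurve(fractions=fr, mcc_at=mcc_at, mcc_auc=auc)


def bin_summary(labels, hard_labels, uncertainty, edges=None) -> BinSummary:
    """Confusion composition of predictions within uncertainty bins.

    Bins are left-closed right-open, last bin closed; defaults to ten equal
    bins on [0, 1] (unit-scaled uncertainty). Per-bin percentages sum to 100
    where the bin is populated.
    """
    y = _as_binary(labels)
    yhat = _as_binary(hard_labels)
    u = _uvalues(uncertainty)
    if edges is None:
        edges = np.linspace(0.0, 1.0, 11)
    edges = np.asarray(edges, dtype=np.float64)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise NonMonotoneEdges("edges must be strictly increasing")
    idx = np.searchsorted(edges, u, side="right") - 1
    idx = np.clip(idx, 0, edges.size - 2)  # closes the last bin
    n_bins = edges.size - 1
    outcome = np.where(
        (y == 1) & (yhat == 1), 0,
        np.where((y == 0) & (yhat == 0), 1, np.where((y == 0) & (yhat == 1), 2, 3)),
    )
    keys = ("tp", "tn", "fp", "fn")
    counts = {k: np.zeros(n_bins, dtype=int) for k in keys}
    for b, o in zip(idx, outcome):
        counts[keys[o]][b] += 1
    totals = sum(counts.values())
    percentages = {
        k: np.where(totals > 0, 100.0 * counts[k] / np.where(totals > 0, totals, 1), 0.0)
        for k in keys
    }
    return BinSummary(edges=edges, counts=counts, totals=totals, percentages=percentages)


def threshold_summary(labels, hard_labels, uncertainty, cut: float):
    """Tally of the sub-threshold subset: (n_below, n_errors, error_rate).

    error_rate is None when nothing falls below the cut.
    """
    y = _as_binary(labels)
    yhat = _as_binary(hard_labels)
    u = _uvalues(uncertainty)
    mask = u < cut
    n_below = int(mask.sum())
    if n_below == 0:
        return 0, 0, None
    n_err = int(np.sum(y[mask] != yhat[mask]))
    return n_below, n_err, n_err / n_below


def compare_runs(metric_a, metric_b):
    """Two-sample t-test on per-seed metric values of two models/methods."""
    res = stats.ttest_ind(np.asarray(metric_a, float), np.asarray(metric_b, float))
    return float(res.statistic), float(res.pvalue)


def stratified_folds(labels, k: int = 3, seed: int = 0):
    """Stratified k-fold index pairs with a fixed shuffle seed."""
    y = _as_binary(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))
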