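"""KNN classification, jackknife cross-validation and the evaluation criteria.

Classification quality is summarized one-vs-rest per class with the
Matthews correlation coefficient (MCC), sensitivity (Sen = TP/(TP+FN)) and
specificity (Spe = TN/(TN+FP)), plus the overall accuracy
Q = sum_k TP_k / N.  A zero denominator leaves the value undefined; such
entries are reported as missing and rendered ``"-"`` in text output, never
as a number.

The jackknife (leave-one-out) test removes each sample in turn, trains the
configured pipeline on the remaining N-1 samples and predicts the held-out
one.  ``strict`` mode refits the KDA reduction inside every fold;
``fast`` mode fits KDA once on the full data and leaves only the KNN
classifier out-of-fold, which is how per-candidate accuracies are scored
inside grid search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .dataset import LabeledDataset

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "knn_predict",
    "loo_knn_counts",
    "jackknife",
    "metrics",
]


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts per class (each quadruple sums to N)."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        totals = self.tp + self.tn + self.fp + self.fn
        if np.unique(totals).size != 1:
            raise ValueError("per-class counts must all sum to the same N")

    @property
    def n_samples(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])

    @property
    def n_classes(self) -> int:
        return self.tp.size

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int | None = None) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if n_classes is None:
            n_classes = int(max(y_true.max(), y_pred.max())) + 1
        tp = np.zeros(n_classes, dtype=int)
        tn = np.zeros(n_classes, dtype=int)
        fp = np.zeros(n_classes, dtype=int)
        fn = np.zeros(n_classes, dtype=int)
        for k in range(n_classes):
            is_k = y_true == k
            pred_k = y_pred == k
            tp[k] = np.sum(is_k & pred_k)
            fn[k] = np.sum(is_k & ~pred_k)
            fp[k] = np.sum(~is_k & pred_k)
            tn[k] = np.sum(~is_k & ~pred_k)
        return cls(tp, tn, fp, fn)


@dataclass
class EvalReport:
    """Per-class MCC/Sen/Spe and overall accuracy Q; ``None`` marks undefined."""

    mcc: list[float | None]
    sen: list[float | None]
    spe: list[float | None]
    q: float
    knn_k: int | None = None

    def to_dict(self, class_names: list[str] | None = None) -> dict:
        """JSON-friendly dict with undefined values rendered as ``"-"``."""
        C = len(self.mcc)
        names = class_names if class_names is not None else [str(k) for k in range(C)]

        def render(vals):
            return {n: ("-" if v is None else round(v, 6)) for n, v in zip(names, vals)}

        out = {
            "sensitivity": render(self.sen),
            "specificity": render(self.spe),
            "mcc": render(self.mcc),
            "overall_accuracy_Q": round(self.q, 6),
        }
        if self.knn_k is not None:
            out["knn_k"] = self.knn_k
        return out


def knn_predict(train_X, train_y, query, k: int) -> int:
    """Majority label among the k nearest training samples (Euclidean).

    Deterministic tie handling: equal distances keep training-set order
    (stable sort); a tied vote goes to the tied class whose representative
    appears earliest among the ordered neighbors (in particular, to the
    class of the single nearest neighbor when it is among the tied).
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    train_y = np.asarray(train_y, dtype=int)
    n = train_X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    query = np.asarray(query, dtype=float).ravel()
    d = np.linalg.norm(train_X - query, axis=1)
    order = np.argsort(d, kind="stable")[:k]
    votes = train_y[order]
    counts = np.bincount(votes)
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if tied.size == 1:
        return int(tied[0])
    for lab in votes:  # earliest neighbor belonging to a tied class wins
        if lab in tied:
            return int(lab)
    raise AssertionError("unreachable: some tied class must appear among the neighbors")


def loo_knn_counts(X, y, k: int, n_classes: int | None = None) -> ConfusionCounts:
    """Leave-one-out KNN confusion counts on a fixed coordinate matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} out of range 1..{n - 1} for leave-one-out")
    D = cdist(X, X)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        d = np.delete(D[i], i)
        labels = np.delete(y, i)
        order = np.argsort(d, kind="stable")[:k]
        votes = labels[order]
        counts = np.bincount(votes)
        best = counts.max()
        tied = np.flatnonzero(counts == best)
        if tied.size == 1:
            preds[i] = tied[0]
        else:
            preds[i] = next(int(lab) for lab in votes if lab in tied)
    if n_classes is None:
        n_classes = int(y.max()) + 1
    return ConfusionCounts.from_predictions(y, preds, n_classes)


def jackknife(
    data: LabeledDataset,
    scale: float,
    d: int,
    knn_k: int = 20,
    mode: str = "strict",
) -> ConfusionCounts:
    """Leave-one-out evaluation of the KDA + KNN pipeline.

    ``strict`` refits KDA on the N-1 retained samples in every fold and
    projects both fold and query with that model; ``fast`` fits KDA once on
    all N samples and only the KNN vote is out-of-fold.

    Raises
    ------
    ValueError
        If removing a sample would empty its class (KDA needs every class
        populated), naming the class.
    """
    from . import kda  # deferred to avoid a cycle at import time

    if mode not in ("strict", "fast"):
        raise ValueError(f"mode must be 'strict' or 'fast', got {mode!r}")
    n = data.n_samples
    if n < data.n_classes + 1:
        raise ValueError("need at least C+1 samples for leave-one-out")

    if mode == "fast":
        model = kda.fit_kda(data, scale, d)
        coords = model.project(data.X)
        return loo_knn_counts(coords, data.y, knn_k, n_classes=data.n_classes)

    sizes = data.class_sizes
    preds = np.empty(n, dtype=int)
    for i in range(n):
        c = data.y[i]
        if sizes[c] == 1:
            name = data.class_names[c] if data.class_names else str(c)
            raise ValueError(f"fold {i} would remove the only sample of class {name!r}")
        keep = np.delete(np.arange(n), i)
        fold = data.subset(keep)
        model = kda.fit_kda(fold, scale, d)
        train_coords = model.project(fold.X)
        query_coords = model.project(data.X[i])
        preds[i] = knn_predict(train_coords, fold.y, query_coords, min(knn_k, n - 1))
    return ConfusionCounts.from_predictions(data.y, preds, data.n_classes)


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def metrics(counts: ConfusionCounts, knn_k: int | None = None, printed_specificity: bool = False) -> EvalReport:
    """Per-class MCC, sensitivity and specificity plus overall accuracy Q.

    ``printed_specificity`` switches to the nonstandard variant
    TN/(TP+FP) for fidelity experiments; the default is the standard
    TN/(TN+FP).  Undefined values (zero denominator) are ``None``.
    """
    mcc: list[float | None] = []
    sen: list[float | None] = []
    spe: list[float | None] = []
    for tp, tn, fp, fn in zip(counts.tp, counts.tn, counts.fp, counts.fn):
        tp, tn, fp, fn = int(tp), int(tn), int(fp), int(fn)
        denom2 = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
        mcc.append(None if denom2 == 0 else (tp * tn - fn * fp) / np.sqrt(denom2))
        sen.append(_safe_div(tp, tp + fn))
        if printed_specificity:
            spe.append(_safe_div(tn, tp + fp))
        else:
            spe.append(_safe_div(tn, tn + fp))
    q = float(counts.tp.sum()) / counts.n_samples
    return EvalReport(mcc=mcc, sen=sen, spe=spe, q=q, knn_k=knn_k)
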