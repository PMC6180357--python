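"""Confusion counts, ROC curves and AUC.

The classification rule is "predict +1 iff score >= tau" (inclusive), and
the ROC curve is the polyline of (FPR, TPR) pairs swept over all
distinguishable thresholds, closed at (0,0) and (1,1); the area under it
(trapezoidal rule) is the headline accuracy number.  AUC computed this way
equals the Mann-Whitney U statistic normalised by n+ * n-, a fact the test
suite checks against a brute-force pairwise count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "RocResult", "confusion", "rates", "roc_auc"]


class UndefinedRateError(ZeroDivisionError):
    """A TPR/FPR denominator is zero (no actual positives / negatives)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tn: int
    fn: int
    fp: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fn + self.fp + self.tp


@dataclass(frozen=True)
class RocResult:
    """thresholds: the sweep (descending score cutoffs); points: (FPR, TPR)
    pairs including the (0,0) and (1,1) closure; auc: trapezoidal area."""

    thresholds: np.ndarray
    points: np.ndarray
    auc: float

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            self.points,
            delimiter=",",
            header="fpr,tpr",
            comments="",
            fmt="%.10g",
        )


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must lie in {-1, +1}")
    return y


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Counts with actual class in columns, predicted class in rows."""
    yt = _check_labels(y_true)
    yp = _check_labels(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tn=int(np.sum((yp < 0) & (yt < 0))),
        fn=int(np.sum((yp < 0) & (yt > 0))),
        fp=int(np.sum((yp > 0) & (yt < 0))),
        tp=int(np.sum((yp > 0) & (yt > 0))),
    )


def rates(c: ConfusionCounts) -> tuple[float, float]:
    """(TPR, FPR) = (TP/(TP+FN), FP/(FP+TN)); a zero denominator raises."""
    if c.tp + c.fn == 0:
        raise UndefinedRateError("TPR undefined: no actual positives")
    if c.fp + c.tn == 0:
        raise UndefinedRateError("FPR undefined: no actual negatives")
    return c.tp / (c.tp + c.fn), c.fp / (c.fp + c.tn)


def roc_auc(scores, y_true) -> RocResult:
    """ROC sweep over the unique scores (ties grouped), AUC by trapezoid.

    Scores may be probabilities or arbitrary real-valued rankings; only
    their order matters, so AUC is invariant under strictly monotone
    transforms.
    """
    y = _check_labels(y_true)
    s = np.asarray(scores, dtype=float).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    npos = int(np.sum(y > 0))
    nneg = int(np.sum(y < 0))
    if npos == 0 or nneg == 0:
        raise ValueError("need at least one positive and one negative label")
    # descending unique thresholds; at threshold tau everything with
    # score >= tau is predicted +1, so cumulative counts give the curve
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp_cum = np.cumsum(y_sorted > 0)
    fp_cum = np.cumsum(y_sorted < 0)
    # group tied scores: keep the last index of each tie block
    last_of_tie = np.r_[np.flatnonzero(np.diff(s_sorted) != 0.0), s.size - 1]
    tpr = tp_cum[last_of_tie] / npos
    fpr = fp_cum[last_of_tie] / nneg
    thresholds = s_sorted[last_of_tie]
    pts = np.column_stack([fpr, tpr])
    pts = np.vstack([[0.0, 0.0], pts])
    if pts[-1, 0] != 1.0 or pts[-1, 1] != 1.0:
        pts = np.vstack([pts, [1.0, 1.0]])
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return RocResult(thresholds=thresholds, points=pts, auc=auc)
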