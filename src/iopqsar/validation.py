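"""Agreement between experimental and model-derived activity estimates.

The headline statistic is the nonparametric Spearman rank correlation
between the experimental binary IOP class and the model's calculated
estimate (the predicted probability of activity by default, hard labels as
an alternative), plus standard binary-classification diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ValidationReport:
    """Spearman rho and confusion-matrix diagnostics."""

    spearman_rho: float
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    n: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def __str__(self) -> str:
        return (
            f"n={self.n}  rho={self.spearman_rho:.4f}  "
            f"accuracy={self.accuracy:.4f}  sensitivity={self.sensitivity:.4f}  "
            f"specificity={self.specificity:.4f}  "
            f"[TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn}]"
        )


def spearman(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Pearson correlation of the average-ranked values; reduces to the
    closed form 1 - 6*sum(d^2)/(n(n^2-1)) when there are no ties.  Raises
    if either vector has zero rank variance (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("Spearman rho undefined: an argument is constant")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def confusion_metrics(y_true, y_pred, scores=None) -> ValidationReport:
    """Confusion counts, accuracy/sensitivity/specificity, and Spearman rho.

    ``scores`` (e.g. predicted probabilities) is what rho is computed
    against; it defaults to the hard predictions.  Sensitivity is with
    respect to class 1 (active).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-d vectors of equal length")
    for name, v in (("y_true", y_true), ("y_pred", y_pred)):
        if set(np.unique(v)) - {0, 1}:
            raise ValueError(f"{name} must be binary (0/1)")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = len(y_true)
    n_pos = tp + fn
    n_neg = tn + fp
    if scores is None:
        scores = y_pred
    try:
        rho = spearman(y_true, np.asarray(scores, dtype=float))
    except ValueError:
        rho = np.nan
    return ValidationReport(
        spearman_rho=rho,
        accuracy=(tp + tn) / n,
        sensitivity=tp / n_pos if n_pos else np.nan,
        specificity=tn / n_neg if n_neg else np.nan,
        tp=tp, fp=fp, tn=tn, fn=fn, n=n,
    )
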