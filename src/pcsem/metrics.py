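"""Multi-label evaluation: threshold-swept precision–recall and trapezoidal AP.

Scores are per-class sigmoid outputs in [0, 1].  For a grid of probability
thresholds (by default an exponential curve between 0 and 1), each threshold
``t`` induces the prediction rule ``score >= t``; precision and recall at
every threshold give the operating points of a PR curve, and the per-class
average precision is the trapezoidal integral of precision over recall
between the boundary values a = 0 and b = 1:

    AP_c = ∫₀¹ f(x_c) dx  ≈  ½ Σₙ (f(x_{n+1}) + f(x_n)) Δx_n

with x the recall and f(x) the precision of class c.  mAP is the unweighted
mean of the per-class APs over classes that have at least one positive label.

Conventions (fixed here, configurable nowhere — they define the metric):
thresholds are closed on the left (``>=``); a threshold that predicts nothing
has precision 1 (the recall-0 anchor); the curve is padded to recall 1 at
threshold 0, where precision equals the class prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "exponential_thresholds", "pr_points", "average_precision",
    "mean_average_precision", "PRCurve", "APResult",
]


def exponential_thresholds(n_points: int = 100, curvature: float = 5.0) -> np.ndarray:
    """Exponentially spaced thresholds t_i = (e^{k u_i} − 1)/(e^k − 1) on [0, 1].

    ``u_i = i/(n_points−1)``; curvature k > 0 concentrates thresholds near 0,
    where sigmoid scores of negatives pile up.  As k → 0 the grid becomes
    uniform.  Endpoints are exactly 0 and 1.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if curvature <= 0:
        raise ValueError("curvature must be > 0")
    u = np.linspace(0.0, 1.0, n_points)
    t = np.expm1(curvature * u) / np.expm1(curvature)
    t[0], t[-1] = 0.0, 1.0
    return t


@dataclass
class PRCurve:
    """Recall-ordered operating points of one class."""

    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray = field(default=None)  # aligned with the unpadded points

    def __post_init__(self):
        self.recall = np.asarray(self.recall, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)


@dataclass
class APResult:
    per_class_ap: np.ndarray
    map: float
    n_points: int
    evaluated_classes: list[int]
    excluded_classes: list[int]

    def to_dict(self) -> dict:
        return {
            "per_class_ap": [float(a) for a in self.per_class_ap],
            "map": float(self.map),
            "n_points": int(self.n_points),
            "evaluated_classes": list(self.evaluated_classes),
            "excluded_classes": list(self.excluded_classes),
        }


def pr_points(scores: np.ndarray, labels: np.ndarray,
              thresholds: np.ndarray | None = None) -> PRCurve:
    """Sweep thresholds over one class's scores and build its PR curve.

    Points are sorted by recall and padded so the curve spans recall 0
    (precision 1) to recall 1 (precision = prevalence, the threshold-0
    operating point).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("average precision is undefined for a class with no "
                         "positive labels; exclude the class upstream")
    if thresholds is None:
        thresholds = exponential_thresholds()
    thresholds = np.asarray(thresholds, dtype=float)

    pred = scores[None, :] >= thresholds[:, None]          # (T, n)
    tp = (pred & (labels == 1)).sum(axis=1).astype(float)
    pp = pred.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pp > 0, tp / np.maximum(pp, 1), 1.0)
    recall = tp / n_pos

    order = np.lexsort((-precision, recall))
    recall, precision, thresholds = recall[order], precision[order], thresholds[order]
    rec = list(recall)
    prec = list(precision)
    if rec[0] > 0:
        rec.insert(0, 0.0)
        prec.insert(0, 1.0)
    if rec[-1] < 1:
        rec.append(1.0)
        prec.append(n_pos / len(labels))
    return PRCurve(np.array(rec), np.array(prec), thresholds)


def average_precision(curve: PRCurve) -> float:
    """Trapezoidal integral of precision over recall; always in [0, 1]."""
    r, p = curve.recall, curve.precision
    if np.any(np.diff(r) < 0):
        raise ValueError("PR curve recall must be nondecreasing")
    return float(np.trapezoid(p, r))


def mean_average_precision(scores: np.ndarray, labels: np.ndarray,
                           thresholds: np.ndarray | None = None) -> APResult:
    """Per-class trapezoidal AP and their unweighted mean.

    ``scores`` and ``labels`` are (n_frames, n_classes).  Classes without a
    single positive label are excluded from the mean and reported in
    ``excluded_classes``.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.atleast_2d(np.asarray(labels))
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must share shape")
    if thresholds is None:
        thresholds = exponential_thresholds()
    n_classes = scores.shape[1]
    aps = np.full(n_classes, np.nan)
    evaluated, excluded = [], []
    for c in range(n_classes):
        if labels[:, c].sum() == 0:
            excluded.append(c)
            continue
        aps[c] = average_precision(pr_points(scores[:, c], labels[:, c], thresholds))
        evaluated.append(c)
    if not evaluated:
        raise ValueError("no class has a positive label; mAP is undefined")
    return APResult(aps, float(np.nanmean(aps[evaluated])), len(thresholds),
                    evaluated, excluded)


def evaluation_report(result: APResult, labels: np.ndarray,
                      class_names: list[str] | None = None):
    """Tabular per-class report (rows: class, AP, n_pos, n_frames)."""
    import pandas as pd

    labels = np.atleast_2d(np.asarray(labels))
    n = labels.shape[0]
    names = class_names or [f"class_{c}" for c in range(labels.shape[1])]
    rows = [{"class": names[c], "ap": float(result.per_class_ap[c]),
             "n_pos": int(labels[:, c].sum()), "n_frames": n}
            for c in range(labels.shape[1])]
    df = pd.DataFrame(rows)
    df.attrs["map"] = result.map
    return df
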