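"""Unbalanced-multiclass performance metrics from confusion matrices.

Four complementary metrics per confusion matrix:

* accuracy — mean per-class recall (average of diagonal row fractions);
  equals the usual trace/total accuracy on balanced test sets,
* balanced accuracy — macro mean over classes of
  (sensitivity + specificity) / 2 in a one-vs-rest reduction,
* F_beta — macro mean of the per-class harmonic mean of precision and
  recall (beta = 1 by default),
* MCC — Gorodkin's multiclass Matthews correlation coefficient in
  [-1, 1], 0 at chance; 0/0 degeneracies map to 0 by convention.

Over a Monte Carlo ensemble of confusion matrices the per-draw metric
vectors form the distributions that are compared between feature
spaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

METRIC_NAMES = ("acc", "bal_acc", "f1", "mcc")


def _check(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    return c


def accuracy(c: np.ndarray) -> float:
    """Mean per-class recall: (1/K) sum_k c_kk / row-sum_k."""
    c = _check(c)
    rows = c.sum(axis=1)
    if np.any(rows == 0):
        raise ValueError("zero row sum: a class is absent from the test set")
    return float(np.mean(np.diag(c) / rows))


def _ovr_counts(c: np.ndarray, k: int) -> tuple[float, float, float, float]:
    tp = c[k, k]
    fn = c[k].sum() - tp
    fp = c[:, k].sum() - tp
    tn = c.sum() - tp - fn - fp
    return tp, tn, fp, fn


def balanced_accuracy(c: np.ndarray) -> float:
    """Macro mean over classes of (sensitivity + specificity) / 2."""
    c = _check(c)
    if np.any(c.sum(axis=1) == 0):
        raise ValueError("zero row sum: a class is absent from the test set")
    vals = []
    for k in range(c.shape[0]):
        tp, tn, fp, fn = _ovr_counts(c, k)
        if tn + fp == 0:
            raise ValueError("specificity undefined: single-class data")
        sen = tp / (tp + fn)
        spe = tn / (tn + fp)
        vals.append((sen + spe) / 2.0)
    return float(np.mean(vals))


def mcc(c: np.ndarray) -> float:
    """Gorodkin's multiclass Matthews correlation coefficient.

    MCC = (c s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))
    with t_k the per-class truth totals, p_k the prediction totals,
    c the correct count and s the grand total; 0/0 -> 0.
    """
    m = _check(c)
    t = m.sum(axis=1)  # truth totals per class (row sums)
    p = m.sum(axis=0)  # prediction totals per class (column sums)
    s = m.sum()
    correct = np.trace(m)
    num = correct * s - float(p @ t)
    den_sq = (s**2 - float(p @ p)) * (s**2 - float(t @ t))
    if den_sq <= 0:
        return 0.0
    return float(num / np.sqrt(den_sq))


def f_beta(c: np.ndarray, beta: float = 1.0) -> float:
    """Macro-averaged F_beta from per-class precision and recall.

    F_k = (1 + beta^2) Pre Rec / (beta^2 Pre + Rec), with F_k = 0 when
    precision + recall = 0 (no true or predicted instances correct).
    """
    c = _check(c)
    if np.any(c.sum(axis=1) == 0):
        raise ValueError("zero row sum: a class is absent from the test set")
    b2 = beta**2
    vals = []
    for k in range(c.shape[0]):
        tp, _, fp, fn = _ovr_counts(c, k)
        pre = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn)
        denom = b2 * pre + rec
        vals.append((1 + b2) * pre * rec / denom if denom > 0 else 0.0)
    return float(np.mean(vals))


def metric_set(c: np.ndarray) -> dict[str, float]:
    """All four metrics for one confusion matrix."""
    return {"acc": accuracy(c), "bal_acc": balanced_accuracy(c),
            "f1": f_beta(c), "mcc": mcc(c)}


@dataclass(frozen=True)
class MetricDistribution:
    """Per-draw metric vectors of one ensemble, with normal-fit summaries."""

    values: pd.DataFrame  # columns acc, bal_acc, f1, mcc; one row per draw

    @property
    def mean(self) -> pd.Series:
        return self.values.mean()

    @property
    def std(self) -> pd.Series:
        return self.values.std(ddof=1) if len(self.values) > 1 else self.values.std(ddof=0)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.std})


def metric_distributions(ensemble) -> MetricDistribution:
    """Compute all four metrics for every confusion matrix of an ensemble.

    ``ensemble`` is any iterable of square count matrices (e.g. a
    ConfusionEnsemble's matrices).
    """
    matrices = getattr(ensemble, "matrices", ensemble)
    rows = [metric_set(c) for c in matrices]
    if not rows:
        raise ValueError("empty ensemble")
    return MetricDistribution(pd.DataFrame(rows, columns=list(METRIC_NAMES)))
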