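"""Regression and classification metrics, and across-years evaluation.

Regression error is always measured on the SCr scale (predictions are
inverted back from 1/SCr first).  Stage classification is scored on the
4x4 confusion matrix with support-weighted averaging over the classes
present in the truth; occurrence classification binarizes stage > 0 and
scores the positive class.  F is the F1 (harmonic mean).  Undefined
ratios (zero denominators) are reported as 0 and flagged through the
support counts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import (mean_absolute_error, mean_squared_error,
                             precision_recall_fscore_support)


@dataclass
class MetricsBundle:
    mse: float
    mae: float
    stage_precision: float
    stage_recall: float
    stage_f: float
    occurrence_precision: float
    occurrence_recall: float
    occurrence_f: float
    n: int
    n_positive: int
    stage_support: dict

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class IntervalSpec:
    """Three ordered, disjoint date ranges covering the study period.

    Boundaries are end-inclusive on the earlier interval's closed end.
    """

    ranges: tuple = (("2004-01-01", "2007-11-30"),
                     ("2007-12-01", "2011-10-31"),
                     ("2011-11-01", "2015-09-30"))
    names: tuple = ("I1", "I2", "I3")

    def assign(self, dates: pd.Series) -> pd.Series:
        """Interval name per date; NaN when outside all intervals."""
        dates = pd.to_datetime(dates)
        out = pd.Series(np.nan, index=dates.index, dtype=object)
        for name, (lo, hi) in zip(self.names, self.ranges):
            mask = (dates >= pd.Timestamp(lo)) & \
                   (dates <= pd.Timestamp(hi) + pd.Timedelta(hours=23))
            out[mask] = name
        return out


def regression_metrics(pred, actual) -> tuple[float, float]:
    """(MSE, MAE) on the SCr scale."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if len(pred) == 0 or len(pred) != len(actual):
        raise ValueError("pred and actual must be equal-length and non-empty")
    return (float(mean_squared_error(actual, pred)),
            float(mean_absolute_error(actual, pred)))


def stage_metrics(pred_stages, true_stages, average: str = "weighted"
                  ) -> tuple[float, float, float, dict]:
    """Multi-class precision/recall/F over the stages present in truth.

    Support-weighted by default (stage 0 dominates); macro via
    ``average='macro'``.  Returns (precision, recall, f, support map).
    """
    pred = np.asarray(pred_stages, dtype=int)
    true = np.asarray(true_stages, dtype=int)
    if len(pred) != len(true):
        raise ValueError("length mismatch")
    labels = np.unique(true)
    p, r, f, support = precision_recall_fscore_support(
        true, pred, labels=labels, average=None, zero_division=0)
    sup = {int(lab): int(s) for lab, s in zip(labels, support)}
    if average == "macro":
        w = np.ones(len(labels)) / len(labels)
    else:
        w = support / support.sum()
    return float(p @ w), float(r @ w), float(f @ w), sup


def occurrence_metrics(pred_stages, true_stages) -> tuple[float, float, float, dict]:
    """Binary precision/recall/F for AKI occurrence (stage > 0 positive).

    When the truth has no positives, recall is undefined and reported
    as 0 with a flag in the support map.
    """
    pred = np.asarray(pred_stages, dtype=int) > 0
    true = np.asarray(true_stages, dtype=int) > 0
    if len(pred) != len(true):
        raise ValueError("length mismatch")
    p, r, f, _ = precision_recall_fscore_support(
        true, pred, labels=[True], average=None, zero_division=0)
    sup = {"positive": int(true.sum()), "negative": int((~true).sum()),
           "recall_defined": bool(true.any())}
    return float(p[0]), float(r[0]), float(f[0]), sup


def evaluate_predictions(pred_scr, pred_stages, actual_scr, true_stages,
                         average: str = "weighted") -> MetricsBundle:
    """Full bundle for one prediction set."""
    mse, mae = regression_metrics(pred_scr, actual_scr)
    sp, sr, sf, sup = stage_metrics(pred_stages, true_stages, average)
    op, orec, of, osup = occurrence_metrics(pred_stages, true_stages)
    return MetricsBundle(
        mse=mse, mae=mae,
        stage_precision=sp, stage_recall=sr, stage_f=sf,
        occurrence_precision=op, occurrence_recall=orec, occurrence_f=of,
        n=len(np.asarray(true_stages)), n_positive=osup["positive"],
        stage_support=sup)


def random_baseline_occurrence_f(true_stages) -> float:
    """Expected F of prevalence-matched random guessing.

    Guessing positive with probability equal to the prevalence p gives
    precision = recall = F = p in expectation.
    """
    true = np.asarray(true_stages, dtype=int) > 0
    return float(true.mean())


def interval_evaluate(matrix, models, cv_config,
                      intervals: IntervalSpec | None = None) -> dict:
    """Run the nested-CV pipeline separately per calendar interval.

    Rows are assigned by their current-SCr date; rows outside every
    interval are counted but not evaluated.  Returns
    {interval: {model: CVReport}} plus an ``unassigned`` count.
    """
    from .models import nested_cv  # local import to avoid a cycle

    intervals = intervals or IntervalSpec()
    assignment = intervals.assign(matrix.meta["t"])
    out = {"unassigned": int(assignment.isna().sum())}
    for name in intervals.names:
        idx = np.flatnonzero((assignment == name).to_numpy())
        sub = matrix.subset(idx)
        out[name] = {m: nested_cv(sub, m, cv_config) for m in
                     (models if isinstance(models, (list, tuple)) else [models])}
    return out
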