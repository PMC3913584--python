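"""Leave-one-out evaluation, confusion counting and AC/SN/SP/P metrics.

The evaluation protocol: each observation is held out once, the scaler
(+ optional forward selection) and classifier are fitted on the remaining
n-1 rows, and the held-out prediction is scored.  The whole LOO pass is
repeated 16 times with per-repetition seeds (only classifier
initialisation varies); per-cell confusion counts are averaged over the
repetitions and the summary metrics are computed FROM the averaged
counts.  "Positive" is the SCD class throughout:

    AC = (TP+TN)/(TP+TN+FP+FN)   SN = TP/(TP+FN)
    SP = TN/(TN+FP)              P  = TP/(TP+FP)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import FeatureTable
from .model import (
    ClassifierSpec,
    make_classifier,
    sequential_forward_selection,
)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "EvaluationRun",
    "loo_evaluate",
    "repeat_evaluation",
    "metrics",
    "risk_trajectory",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: float
    tn: float
    fp: float
    fn: float

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float  # percent
    sensitivity: float
    specificity: float
    precision: float


@dataclass
class EvaluationRun:
    per_repetition: list[ConfusionCounts]
    averaged: ConfusionCounts
    report: MetricsReport
    interval_index: int = 0
    per_repetition_reports: list[MetricsReport] = field(default_factory=list)


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """AC/SN/SP/P in percent, from (possibly averaged, hence real) counts."""
    if counts.total <= 0:
        raise ValueError("empty confusion counts")

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"zero denominator in {name}; reported as nan")
            return float("nan")
        return 100.0 * num / den

    return MetricsReport(
        accuracy=ratio(counts.tp + counts.tn, counts.total, "accuracy"),
        sensitivity=ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        specificity=ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        precision=ratio(counts.tp, counts.tp + counts.fp, "precision"),
    )


def loo_evaluate(
    table: FeatureTable,
    spec: ClassifierSpec,
    seed: int = 0,
    select_features: bool = False,
) -> ConfusionCounts:
    """One leave-one-out pass; returns integer confusion counts."""
    X, y = table.to_arrays()
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 observations for LOO")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    tp = tn = fp = fn = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        cols = np.arange(X.shape[1])
        if select_features:
            train_rows = [table.rows[j] for j in range(n) if j != i]
            sub = FeatureTable(rows=train_rows, feature_names=table.feature_names)
            sel = sequential_forward_selection(sub, spec, seed=seed)
            name_to_idx = {nm: k for k, nm in enumerate(table.feature_names)}
            cols = np.array([name_to_idx[nm] for nm in sel.selected])
        clf = make_classifier(spec, seed=seed)
        clf.fit(X[np.ix_(mask, cols)], y[mask])
        pred = int(clf.predict(X[i : i + 1, cols])[0])
        if y[i] == 1:
            tp, fn = (tp + 1, fn) if pred == 1 else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if pred == 0 else (tn, fp + 1)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def repeat_evaluation(
    table: FeatureTable,
    spec: ClassifierSpec,
    n_repeats: int = 16,
    base_seed: int = 0,
    select_features: bool = False,
    interval_index: int = 0,
) -> EvaluationRun:
    """``n_repeats`` LOO passes (seeds base_seed+1 .. base_seed+n_repeats).

    Only classifier initialisation differs between repetitions, so a
    deterministic classifier (k-NN) yields identical rows.  The headline
    metrics come from the averaged counts; per-repetition metrics are also
    kept.
    """
    runs = [
        loo_evaluate(table, spec, seed=base_seed + r + 1, select_features=select_features)
        for r in range(n_repeats)
    ]
    averaged = ConfusionCounts(
        tp=float(np.mean([c.tp for c in runs])),
        tn=float(np.mean([c.tn for c in runs])),
        fp=float(np.mean([c.fp for c in runs])),
        fn=float(np.mean([c.fn for c in runs])),
    )
    return EvaluationRun(
        per_repetition=runs,
        averaged=averaged,
        report=metrics(averaged),
        interval_index=interval_index,
        per_repetition_reports=[metrics(c) for c in runs],
    )


def risk_trajectory(windows: np.ndarray, model) -> np.ndarray:
    """Per-window event probability (percent) from a trained classifier.

    ``windows`` is an (n_windows, n_features) array ordered from the
    earliest interval (4th minute) to the latest (1st minute before the
    event).  Monotonicity is an empirical tendency, not enforced.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    if windows.shape[0] < 1:
        raise ValueError("need at least one window")
    if not hasattr(model, "predict_score") or not _is_fitted(model):
        raise ValueError("risk_trajectory needs a trained classifier")
    return 100.0 * model.predict_score(windows)


def _is_fitted(model) -> bool:
    return any(
        hasattr(model, attr) for attr in ("weights_", "X_")
    )
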