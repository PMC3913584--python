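"""Model/Results interface over the classification-evaluation layer.

``ScdRiskModel`` is constructed from a feature table (or pandas
DataFrame) and bundles the classifier choice, optional wrapper feature
selection and the repeated leave-one-out protocol; ``fit()`` returns an
``ScdRiskResults`` carrying the per-repetition confusion counts, the
averaged counts, the AC/SN/SP/P summary and a final classifier trained on
all rows for prospective prediction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import EvaluationRun, metrics, repeat_evaluation, risk_trajectory
from .io import FEATURE_NAMES, FeatureRow, FeatureTable
from .model import ClassifierSpec, MlpSpec, make_classifier, sequential_forward_selection

__all__ = ["ScdRiskModel", "ScdRiskResults"]


class ScdRiskModel:
    """Binary SCD-risk classifier with a repeated-LOO evaluation protocol.

    Parameters
    ----------
    table : FeatureTable
        Labelled 13-feature observations (label "scd" is the positive class).
    classifier : MlpSpec or KnnSpec
        Which classifier to wrap and its hyperparameters.
    select_features : bool
        Run sequential forward selection inside every training fold.
    """

    def __init__(
        self,
        table: FeatureTable,
        classifier: ClassifierSpec = MlpSpec(),
        select_features: bool = False,
    ):
        self.table = table
        self.classifier = classifier
        self.select_features = select_features

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        classifier: ClassifierSpec = MlpSpec(),
        select_features: bool = False,
    ) -> "ScdRiskModel":
        """Build from a DataFrame with the 13 feature columns and a label column."""
        rows = [
            FeatureRow(
                subject_id=str(rec.get("subject_id", i)),
                channel_id=str(rec.get("channel_id", "0")),
                interval_index=int(rec.get("interval_index", 0)),
                features={name: float(rec[name]) for name in FEATURE_NAMES},
                label=str(rec["label"]),
            )
            for i, rec in enumerate(df.to_dict("records"))
        ]
        return cls(FeatureTable(rows=rows), classifier, select_features)

    def fit(self, n_repeats: int = 16, seed: int = 0) -> "ScdRiskResults":
        """Run the repeated-LOO protocol and train the final classifier."""
        run = repeat_evaluation(
            self.table,
            self.classifier,
            n_repeats=n_repeats,
            base_seed=seed,
            select_features=self.select_features,
        )
        X, y = self.table.to_arrays()
        final = make_classifier(self.classifier, seed=seed)
        final.fit(X, y)
        return ScdRiskResults(self, run, final, seed=seed)


class ScdRiskResults:
    """Estimates and diagnostics from :meth:`ScdRiskModel.fit`."""

    def __init__(self, model: ScdRiskModel, run: EvaluationRun, classifier, seed: int):
        self.model = model
        self.run = run
        self.classifier = classifier
        self.seed = seed
        self.counts = run.averaged
        self.report = run.report

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    def counts_frame(self) -> pd.DataFrame:
        """Per-repetition TP/TN/FP/FN plus the averaged column."""
        data = {
            str(i + 1): [c.tp, c.tn, c.fp, c.fn]
            for i, c in enumerate(self.run.per_repetition)
        }
        data["Average"] = [
            self.counts.tp,
            self.counts.tn,
            self.counts.fp,
            self.counts.fn,
        ]
        return pd.DataFrame(data, index=["TP", "TN", "FP", "FN"])

    def selected_features(self) -> list[str]:
        """Forward-selection ranking on the full table (diagnostic)."""
        return sequential_forward_selection(
            self.model.table, self.model.classifier, seed=self.seed
        ).selected

    def predict(self, X: np.ndarray) -> np.ndarray:
        """0/1 class predictions from the final all-rows classifier."""
        return self.classifier.predict(X)

    def risk_trajectory(self, windows: np.ndarray) -> np.ndarray:
        """Per-minute event probability (%) for pre-event feature windows."""
        return risk_trajectory(windows, self.classifier)

    def summary(self) -> str:
        n = len(self.model.table)
        spec = self.model.classifier
        lines = [
            "SCD risk model — repeated leave-one-out evaluation",
            "=" * 52,
            f"Observations:        {n}  (positive class: scd)",
            f"Classifier:          {type(spec).__name__} {spec}",
            f"Repetitions:         {len(self.run.per_repetition)}",
            f"Feature selection:   {'per-fold forward' if self.model.select_features else 'off'}",
            "-" * 52,
            f"Averaged counts:     TP={self.counts.tp:.3f}  TN={self.counts.tn:.3f}  "
            f"FP={self.counts.fp:.3f}  FN={self.counts.fn:.3f}",
            f"Accuracy:            {self.report.accuracy:.2f} %",
            f"Sensitivity:         {self.report.sensitivity:.2f} %",
            f"Specificity:         {self.report.specificity:.2f} %",
            f"Precision:           {self.report.precision:.2f} %",
            "=" * 52,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<ScdRiskResults n={len(self.model.table)} "
            f"accuracy={self.report.accuracy:.2f}%>"
        )
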