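"""Model / Results objects tying the pipeline together.

:class:`CellularUptakeSAR` holds a labeled descriptor dataset and a
configuration; :meth:`fit` runs the full workflow — stratified train/test
split, recursive feature elimination with random-forest importances, final
forest on the selected descriptors, confusion-matrix statistics for the
training, test and complete sets, stratified k-fold cross-validation, and a
per-class leverage applicability-domain assessment of the test set — and
returns a :class:`SARResults` with a Table-style ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import descriptor_table
from .domain import ADReport, ad_assess
from .metrics import MetricsReport, compute_metrics, confusion_counts, metrics_table
from .pipeline import (
    CVResult,
    LabeledDataset,
    PipelineConfig,
    RFEResult,
    SplitResult,
    binarize_uptake,
    cross_validate,
    rf_train,
    rfe_rank,
    split_dataset,
)
from .structure_io import EndpointTable, Molecule

__all__ = ["CellularUptakeSAR", "SARResults"]


class CellularUptakeSAR:
    """Random-forest nano-SAR classifier on norm-index descriptors."""

    def __init__(self, data: LabeledDataset, config: PipelineConfig | None = None):
        self.data = data
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        id_col: str | None = "id",
        config: PipelineConfig | None = None,
    ) -> "CellularUptakeSAR":
        """Build from a flat table: descriptor columns plus a binary label column."""
        df = df.copy()
        ids = [str(i) for i in (df.pop(id_col) if id_col and id_col in df.columns else df.index)]
        y = df.pop(label_col).to_numpy()
        return cls(LabeledDataset(X=df, y=y, ids=ids), config=config)

    @classmethod
    def from_molecules(
        cls,
        molecules: Sequence[Molecule],
        endpoints: EndpointTable,
        threshold_particles: float = 5000,
        config: PipelineConfig | None = None,
    ) -> "CellularUptakeSAR":
        """Compute descriptors and binarize the uptake endpoint by id join."""
        X = descriptor_table(molecules)
        uptake_by_id = endpoints.to_dict()
        missing = [i for i in X.index if i not in uptake_by_id]
        if missing:
            raise ValueError(f"no endpoint value for structure id(s): {missing[:5]}")
        y = binarize_uptake(
            np.array([uptake_by_id[i] for i in X.index]), threshold_particles
        )
        return cls(
            LabeledDataset(X=X.reset_index(drop=True), y=y, ids=list(X.index)), config=config
        )

    def fit(self, pre_split: SplitResult | None = None) -> "SARResults":
        split = pre_split or split_dataset(
            self.data, self.config.test_fraction, self.config.seed, self.config.stratified
        )
        rfe = rfe_rank(split.train, self.config)
        train_sel = split.train.subset_columns(rfe.selected)
        test_sel = split.test.subset_columns(rfe.selected)
        clf = rf_train(train_sel, self.config)

        pred_train = clf.predict(train_sel.X.to_numpy())
        pred_test = clf.predict(test_sel.X.to_numpy())
        metrics = {
            "Training set": compute_metrics(confusion_counts(train_sel.y, pred_train)),
            "Test set": compute_metrics(confusion_counts(test_sel.y, pred_test)),
            "Complete": compute_metrics(
                confusion_counts(
                    np.concatenate([train_sel.y, test_sel.y]),
                    np.concatenate([pred_train, pred_test]),
                )
            ),
        }
        cv = cross_validate(
            train_sel, k=self.config.cv_folds, seed=self.config.seed, config=self.config
        )
        ad = ad_assess(train_sel, test_sel.X, query_ids=test_sel.ids, policy="range")
        return SARResults(
            model=self, split=split, rfe=rfe, classifier=clf, metrics=metrics, cv=cv, ad=ad
        )


@dataclass
class SARResults:
    """Fitted-model artifacts: selection, classifier, statistics, domain."""

    model: CellularUptakeSAR
    split: SplitResult
    rfe: RFEResult
    classifier: object
    metrics: dict[str, MetricsReport]
    cv: CVResult
    ad: ADReport

    @property
    def selected_descriptors(self) -> list[str]:
        return list(self.rfe.selected)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predict labels for new samples; refuses mismatched columns."""
        if list(X.columns) != self.selected_descriptors:
            missing = set(self.selected_descriptors) - set(X.columns)
            if missing:
                raise ValueError(f"missing selected descriptor column(s): {sorted(missing)}")
            X = X[self.selected_descriptors]
        return self.classifier.predict(X.to_numpy())

    def summary(self) -> str:
        lines = [
            "Cellular-uptake nano-SAR (random forest on norm-index descriptors)",
            f"selected descriptors ({len(self.selected_descriptors)}): "
            + ", ".join(self.selected_descriptors),
            f"{self.model.config.cv_folds}-fold CV accuracy (training set): "
            f"{self.cv.mean_accuracy:.3f}",
            f"test samples in applicability domain: "
            f"{int(self.ad.table.groupby('id')['in_domain'].all().sum())} / "
            f"{self.ad.table['id'].nunique()}",
            "",
            metrics_table(self.metrics),
        ]
        return "\n".join(lines)
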