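"""Classification pipeline: binarization, splitting, random forest, RF-RFE.

The endpoint (log10 particles per cell) is binarized at 5000 particles per
cell.  A stratified random split yields training and test sets; feature
selection runs recursive feature elimination with a random-forest importance
ranking: fit the forest, record the cross-validated accuracy of the current
feature subset, drop the single least-important descriptor, repeat until the
set is empty.  The selected subset is the smallest one whose CV accuracy is
within one standard error of the curve maximum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

from .metrics import MetricsReport, compute_metrics, confusion_counts

__all__ = [
    "PipelineConfig",
    "LabeledDataset",
    "SplitResult",
    "RFEResult",
    "CVResult",
    "binarize_uptake",
    "split_dataset",
    "rf_train",
    "rfe_rank",
    "cross_validate",
]

UPTAKE_THRESHOLD_PARTICLES = 5000


@dataclass
class PipelineConfig:
    """Tunable modelling knobs with their defaults.

    n_trees=500 with sqrt(p) features per split and unlimited depth is a
    standard strong forest for ~100-sample problems; rfe_step=1 eliminates
    one descriptor per round; selection_rule "one_se" picks the smallest
    subset within one standard error of the best CV accuracy ("max" picks
    the outright best, smallest on ties).
    """

    seed: int = 0
    test_fraction: float = 20 / 109
    n_trees: int = 500
    rfe_step: int = 1
    cv_folds: int = 5
    selection_rule: str = "one_se"
    stratified: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


@dataclass
class LabeledDataset:
    """Descriptor matrix with binary labels and sample ids."""

    X: pd.DataFrame
    y: np.ndarray
    ids: list[str]
    planted: tuple[str, ...] = ()  # ground-truth informative descriptors, if known

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if self.X.isna().any().any():
            raise ValueError("descriptor matrix contains missing values")
        if self.X.columns.duplicated().any():
            raise ValueError("descriptor column names must be unique")
        if len(self.y) != len(self.X) or len(self.ids) != len(self.X):
            raise ValueError("X, y and ids must agree in length")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary {0, 1}")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.X.columns)

    def subset_rows(self, index: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(index)
        return LabeledDataset(
            X=self.X.iloc[idx].copy(),
            y=self.y[idx],
            ids=[self.ids[i] for i in idx],
            planted=self.planted,
        )

    def subset_columns(self, names: Sequence[str]) -> "LabeledDataset":
        return LabeledDataset(X=self.X[list(names)].copy(), y=self.y, ids=list(self.ids), planted=self.planted)


@dataclass
class SplitResult:
    train: LabeledDataset
    test: LabeledDataset
    seed: int


@dataclass
class RFEResult:
    """Elimination ranking (most important first), CV curve and selection."""

    ranking: list[str]
    performance_curve: list[tuple[int, float]]
    selected: list[str]
    curve_se: list[float] = field(default_factory=list)


@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    mean_accuracy: float

    @property
    def fold_accuracies(self) -> list[float]:
        return [r.ACC for r in self.fold_reports]


def binarize_uptake(uptake: float, threshold_particles: float = UPTAKE_THRESHOLD_PARTICLES) -> int:
    """1 when uptake exceeds log10(threshold) particles per cell, else 0."""
    u = np.asarray(uptake, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("uptake values must be finite")
    labels = (u > math.log10(threshold_particles)).astype(int)
    return int(labels) if labels.ndim == 0 else labels


def split_dataset(
    d: LabeledDataset, test_fraction: float, seed: int, stratified: bool = True
) -> SplitResult:
    """Reproducible random train/test split, stratified by class by default."""
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    idx = np.arange(d.n_samples)
    try:
        train_idx, test_idx = train_test_split(
            idx,
            test_size=test_fraction,
            random_state=seed,
            stratify=d.y if stratified else None,
            shuffle=True,
        )
    except ValueError as exc:
        raise ValueError(f"stratified split failed: {exc}") from exc
    train, test = d.subset_rows(np.sort(train_idx)), d.subset_rows(np.sort(test_idx))
    if stratified and (len(set(train.y)) < 2 or len(set(test.y)) < 2):
        raise ValueError("a class is absent from one partition")
    return SplitResult(train=train, test=test, seed=seed)


def rf_train(train: LabeledDataset, config: PipelineConfig | None = None) -> RandomForestClassifier:
    """Fit the random forest; deterministic for a fixed config seed."""
    config = config or PipelineConfig()
    if len(np.unique(train.y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features="sqrt",
        max_depth=None,
        random_state=config.seed,
    )
    clf.fit(train.X.to_numpy(), train.y)
    return clf


def cross_validate(d: LabeledDataset, k: int = 5, seed: int = 0, config: PipelineConfig | None = None) -> CVResult:
    """Stratified k-fold cross-validation; per-fold metrics plus mean ACC."""
    if k < 2:
        raise ValueError("k-fold cross-validation needs k >= 2")
    counts = np.bincount(d.y, minlength=2)
    if k > counts[counts > 0].min():
        raise ValueError(f"k={k} exceeds the smallest class count {counts[counts > 0].min()}")
    config = config or PipelineConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for train_idx, test_idx in skf.split(d.X, d.y):
        clf = rf_train(d.subset_rows(train_idx), config)
        pred = clf.predict(d.X.iloc[test_idx].to_numpy())
        reports.append(compute_metrics(confusion_counts(d.y[test_idx], pred)))
    return CVResult(fold_reports=reports, mean_accuracy=float(np.mean([r.ACC for r in reports])))


def _cv_accuracies(d: LabeledDataset, config: PipelineConfig) -> np.ndarray:
    k = min(config.cv_folds, int(np.bincount(d.y, minlength=2)[np.bincount(d.y, minlength=2) > 0].min()))
    k = max(k, 2)
    result = cross_validate(d, k=k, seed=config.seed, config=config)
    return np.array(result.fold_accuracies)


def rfe_rank(d: LabeledDataset, config: PipelineConfig | None = None) -> RFEResult:
    """Recursive feature elimination with random-forest importances.

    Iterates from the full descriptor set down to a single descriptor: at
    each size, record the subset's cross-validated accuracy, fit the forest
    on all rows, and drop the least-important descriptor (importance ties
    broken by dropping the later name in canonical column order).  The
    returned ranking lists descriptors from most important (eliminated last)
    to least; ``selected`` follows the configured selection rule.
    """
    config = config or PipelineConfig()
    names = d.descriptor_names
    if len(names) < 1:
        raise ValueError("need at least one descriptor")
    order = {name: pos for pos, name in enumerate(names)}
    current = list(names)
    eliminated: list[str] = []
    curve: list[tuple[int, float]] = []
    curve_se: list[float] = []
    subsets: dict[int, list[str]] = {}
    while current:
        sub = d.subset_columns(current)
        accs = _cv_accuracies(sub, config)
        curve.append((len(current), float(accs.mean())))
        curve_se.append(float(accs.std(ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0)
        subsets[len(current)] = list(current)
        if len(current) == 1:
            eliminated.append(current.pop())
            break
        clf = rf_train(sub, config)
        importances = clf.feature_importances_
        # least important; on ties drop the later descriptor in canonical order
        min_imp = importances.min()
        tied = [name for name, imp in zip(current, importances) if imp <= min_imp + 1e-12]
        victim = max(tied, key=lambda name: order[name])
        current.remove(victim)
        eliminated.append(victim)
    ranking = list(reversed(eliminated))
    selected = _select_subset(curve, curve_se, subsets, config.selection_rule)
    return RFEResult(ranking=ranking, performance_curve=curve, selected=selected, curve_se=curve_se)


def _select_subset(
    curve: list[tuple[int, float]],
    curve_se: list[float],
    subsets: dict[int, list[str]],
    rule: str,
) -> list[str]:
    sizes = np.array([s for s, _ in curve])
    accs = np.array([a for _, a in curve])
    best = int(np.argmax(accs))
    if rule == "max":
        threshold = accs[best]
    elif rule == "one_se":
        threshold = accs[best] - curve_se[best]
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    eligible = sizes[accs >= threshold - 1e-12]
    return subsets[int(eligible.min())]
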