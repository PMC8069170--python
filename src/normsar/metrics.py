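"""Binary-classification validation statistics.

Sensitivity SE = TP/(TP+FN), specificity SP = TN/(TN+FP), accuracy
ACC = (TP+TN)/total and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP)).

The positive class is label 1.  A statistic whose denominator vanishes is
reported as undefined (``None``), never silently substituted with 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts", "compute_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    counts: ConfusionCounts
    SE: float | None
    SP: float | None
    ACC: float
    MCC: float | None

    def to_json(self) -> str:
        c = self.counts
        return json.dumps(
            {
                "counts": {"TP": c.TP, "FP": c.FP, "TN": c.TN, "FN": c.FN},
                "se": self.SE,
                "sp": self.SP,
                "acc": self.ACC,
                "mcc": self.MCC,
            }
        )

    def row(self, label: str) -> str:
        """One table row, metrics at 3 decimal places ('undefined' if so)."""
        def fmt(v: float | None) -> str:
            return "undefined" if v is None else f"{v:.3f}"

        return (
            f"{label:<14s}{self.counts.total:>5d}  "
            f"{fmt(self.SE):>9s}  {fmt(self.SP):>9s}  {fmt(self.ACC):>9s}  {fmt(self.MCC):>9s}"
        )


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Confusion-matrix counts for binary labels with positive class 1."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError(f"label vectors must be equal-length 1-D, got {t.shape} vs {p.shape}")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary {0, 1}")
    return ConfusionCounts(
        TP=int(((t == 1) & (p == 1)).sum()),
        FP=int(((t == 0) & (p == 1)).sum()),
        TN=int(((t == 0) & (p == 0)).sum()),
        FN=int(((t == 1) & (p == 0)).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """SE, SP, ACC and MCC from confusion counts.

    Raises ``ValueError`` on an empty matrix; individual statistics with a
    zero denominator come back as ``None`` (undefined).
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics for zero evaluated samples")
    se = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    sp = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else None
    acc = (c.TP + c.TN) / c.total
    denom = (c.TP + c.FN) * (c.TP + c.FP) * (c.TN + c.FN) * (c.TN + c.FP)
    mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom) if denom > 0 else None
    return MetricsReport(counts=c, SE=se, SP=sp, ACC=acc, MCC=mcc)


def metrics_table(rows: dict[str, MetricsReport]) -> str:
    """Human-readable table: Sub-Set, n, SE, SP, ACC, MCC (3 d.p.)."""
    header = f"{'Sub-Set':<14s}{'n':>5s}  {'SE':>9s}  {'SP':>9s}  {'ACC':>9s}  {'MCC':>9s}"
    lines = [header, "-" * len(header)]
    lines += [report.row(label) for label, report in rows.items()]
    return "\n".join(lines)
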