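"""Leverage-based applicability domain, evaluated per class.

The leverage of a query row x against a training descriptor matrix X is the
quadratic form h = x^T (X^T X)^{-1} x; for a training row it equals the
corresponding diagonal entry of the hat matrix X (X^T X)^{-1} X^T.  A
prediction is trusted only for queries whose leverage falls inside the
training domain.  Two policies are provided: ``range`` (in-domain when
h <= max training leverage of the class) and ``warning_leverage``
(h <= h* = 3 p' / n).  The assessment is run separately for each class
(positive and negative training submatrices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import LabeledDataset

__all__ = ["ADReport", "leverage", "ad_assess"]


@dataclass
class ADReport:
    """Per-query leverages and in/out-of-domain flags, one row per (id, class)."""

    table: pd.DataFrame  # columns: id, class, leverage, in_domain, policy
    training_range: dict[int, tuple[float, float]]
    warning_leverage: dict[int, float]

    @property
    def all_in_domain(self) -> bool:
        return bool(self.table["in_domain"].all())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _xtx_inv(X: np.ndarray) -> np.ndarray:
    n, p = X.shape
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        warnings.warn("X^T X is rank-deficient; using the Moore-Penrose pseudo-inverse")
        return np.linalg.pinv(xtx)
    return np.linalg.inv(xtx)


def leverage(X: np.ndarray, x: np.ndarray) -> float | np.ndarray:
    """Leverage h = x^T (X^T X)^{-1} x of one or more query rows.

    ``x`` may be a single row (returns a scalar) or a 2-D block of rows
    (returns a vector).  Columns must match X; a rank-deficient X^T X falls
    back to the pseudo-inverse with a warning.
    """
    X = np.asarray(X, dtype=float)
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    q = np.atleast_2d(x)
    if q.shape[1] != X.shape[1]:
        raise ValueError(f"query has {q.shape[1]} columns, training matrix has {X.shape[1]}")
    inv = _xtx_inv(X)
    h = np.einsum("ij,jk,ik->i", q, inv, q)
    return float(h[0]) if single else h


def ad_assess(
    train: LabeledDataset,
    query_X: pd.DataFrame,
    query_ids: list[str] | None = None,
    policy: str = "range",
    add_intercept: bool = False,
) -> ADReport:
    """Assess queries against each class's training leverage domain.

    ``range`` flags a query in-domain when its leverage does not exceed the
    maximum training leverage of the class; ``warning_leverage`` compares
    against h* = 3 p' / n instead (p' counts the optional intercept column).
    """
    if policy not in {"range", "warning_leverage"}:
        raise ValueError(f"unknown AD policy {policy!r}")
    cols = train.descriptor_names
    if list(query_X.columns) != cols:
        raise ValueError("query columns do not match training descriptor columns")
    ids = query_ids if query_ids is not None else [str(i) for i in query_X.index]

    rows = []
    training_range: dict[int, tuple[float, float]] = {}
    warning: dict[int, float] = {}
    for cls in sorted(np.unique(train.y)):
        mask = train.y == cls
        Xc = train.X.to_numpy()[mask]
        if Xc.shape[0] == 0:
            raise ValueError(f"no training samples for class {cls}")
        if Xc.shape[0] < Xc.shape[1]:
            raise ValueError(
                f"class {cls}: {Xc.shape[0]} training rows < {Xc.shape[1]} descriptor columns; "
                "assess in the selected-descriptor subspace"
            )
        Q = query_X.to_numpy(float)
        if add_intercept:
            Xc = np.hstack([np.ones((Xc.shape[0], 1)), Xc])
            Q = np.hstack([np.ones((Q.shape[0], 1)), Q])
        h_train = leverage(Xc, Xc)
        training_range[int(cls)] = (float(h_train.min()), float(h_train.max()))
        warning[int(cls)] = 3.0 * Xc.shape[1] / Xc.shape[0]
        h_query = leverage(Xc, Q)
        cut = h_train.max() if policy == "range" else warning[int(cls)]
        for sid, h in zip(ids, h_query):
            rows.append(
                {"id": sid, "class": int(cls), "leverage": float(h),
                 "in_domain": bool(h <= cut + 1e-12), "policy": policy}
            )
    return ADReport(
        table=pd.DataFrame(rows), training_range=training_range, warning_leverage=warning
    )
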