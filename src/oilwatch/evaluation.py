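"""Shared evaluation machinery: confusion-matrix metrics, stratified splits,
cross-validation folds, and the printed-table consistency calculator.

Conventions follow the surveillance setting throughout: *sensitivity* is the
probability of identifying the positive class (an edible-oil-related item, or
a suspicious manufacturer-month), *specificity* the probability of identifying
the negative class, and *error rate* the total misclassification proportion.
Percentages are rendered half-up to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "EvalReport",
    "metrics_from_confusion",
    "report_from_predictions",
    "implied_error_rate",
    "make_cv_folds",
    "stratified_split",
    "format_percent",
]


def format_percent(fraction: float, decimals: int = 2) -> str:
    """Render a fraction in [0, 1] as a percentage string, rounded half-up.

    ``format_percent(2/452)`` -> ``"0.44%"``.
    """
    q = Decimal(1).scaleb(-decimals)
    pct = (Decimal(repr(float(fraction))) * 100).quantize(q, rounding=ROUND_HALF_UP)
    return f"{pct}%"


@dataclass(frozen=True)
class EvalReport:
    """Binary-classification performance summary built from confusion counts.

    Invariants: ``tp + fn == n_pos``, ``tn + fp == n_neg``,
    ``sensitivity == tp / n_pos``, ``specificity == tn / n_neg``,
    ``error_rate == (fn + fp) / (n_pos + n_neg)``.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    method: str = ""
    seed: int | None = None
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"confusion count {name} must be a non-negative integer, got {v}")
        if self.n_pos == 0:
            raise ValueError("no positive examples (tp + fn == 0); metrics undefined")
        if self.n_neg == 0:
            raise ValueError("no negative examples (tn + fp == 0); metrics undefined")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_pos

    @property
    def specificity(self) -> float:
        return self.tn / self.n_neg

    @property
    def error_rate(self) -> float:
        return (self.fn + self.fp) / self.n

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "error_rate": self.error_rate,
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }
        if self.seed is not None:
            d["seed"] = self.seed
        d.update(self.extra)
        return d

    def summary(self) -> str:
        lines = [
            f"method:      {self.method or '-'}",
            f"n:           {self.n} ({self.n_pos} positive / {self.n_neg} negative)",
            f"sensitivity: {format_percent(self.sensitivity)}  (tp={self.tp}, fn={self.fn})",
            f"specificity: {format_percent(self.specificity)}  (tn={self.tn}, fp={self.fp})",
            f"error rate:  {format_percent(self.error_rate)}",
        ]
        return "\n".join(lines)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.summary()


def metrics_from_confusion(
    tp: int, fn: int, tn: int, fp: int, method: str = "", seed: int | None = None
) -> EvalReport:
    """Build an :class:`EvalReport` from raw confusion counts."""
    return EvalReport(tp=tp, fn=fn, tn=tn, fp=fp, method=method, seed=seed)


def report_from_predictions(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    positive: object = 1,
    method: str = "",
    seed: int | None = None,
) -> EvalReport:
    """Confusion-count bookkeeping over paired label vectors."""
    t = np.asarray(y_true) == positive
    p = np.asarray(y_pred) == positive
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum(t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))
    return EvalReport(tp=tp, fn=fn, tn=tn, fp=fp, method=method, seed=seed)


def implied_error_rate(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> float:
    """Error rate implied by printed sensitivity/specificity and class sizes.

    Published tables report sensitivity and specificity to limited precision;
    the underlying error counts are recovered as the nearest integers
    ``fn = round((1 - se) * n_pos)`` and ``fp = round((1 - sp) * n_neg)``
    (half-up), from which the total error rate ``(fn + fp) / (n_pos + n_neg)``
    follows. This is the consistency check used to audit a performance table
    whose raw confusion matrices are not published.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive integers")
    fn = math.floor((1.0 - sensitivity) * n_pos + 0.5)
    fp = math.floor((1.0 - specificity) * n_neg + 0.5)
    return (fn + fp) / (n_pos + n_neg)


def make_cv_folds(labels: Sequence[object], n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified, disjoint, exhaustive fold assignment.

    Returns an integer array ``folds`` with ``folds[i]`` in ``[0, n_folds)``.
    Raises when any class has fewer members than ``n_folds``.
    """
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot form {n_folds} stratified folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[test_idx] = k
    return folds


def stratified_split(
    labels: Sequence[object], test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split (default 8:2)."""
    y = np.asarray(labels)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=y
    )
    return np.sort(train_idx), np.sort(test_idx)
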