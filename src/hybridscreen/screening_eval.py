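"""Screening performance: cutoff classification, the five standard metrics
(accuracy, sensitivity, specificity, PPV, NPV), and per-item validity
coefficients."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .irt_core import ResponseMatrix

__all__ = [
    "ConfusionCounts",
    "classify",
    "metrics",
    "validity_coefficients",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 screening table; positive = diagnosed PTSD."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, truth, predicted) -> "ConfusionCounts":
        """Build counts from boolean (or 0/1) arrays: True = positive."""
        t = np.asarray(truth, dtype=bool)
        p = np.asarray(predicted, dtype=bool)
        if t.shape != p.shape:
            raise ValueError("truth and prediction must align")
        return cls(
            tp=int(np.sum(t & p)), fp=int(np.sum(~t & p)),
            tn=int(np.sum(~t & ~p)), fn=int(np.sum(t & ~p)),
        )


def classify(theta_hats, cutoff: float, positive_if_geq: bool = True) -> np.ndarray:
    """Screen latent-trait estimates against a cutoff.

    The boundary is inclusive by default: theta_hat == cutoff is called
    positive. Returns a boolean array (True = positive).
    """
    t = np.asarray(theta_hats, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("latent estimates must be finite")
    return t >= cutoff if positive_if_geq else t > cutoff


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """The five screening metrics; a metric with a zero denominator is NaN."""
    if c.n == 0:
        raise ValueError("empty confusion table")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return {
        "accuracy": (c.tp + c.tn) / c.n,
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
    }


def validity_coefficients(responses: ResponseMatrix, criterion) -> dict[str, float]:
    """Point-biserial validity coefficient per item.

    Pearson correlation between each item's 0/1 responses and the criterion
    score (e.g. the estimated latent trait or a clinical scale). Items with a
    single observed category, or a constant criterion, are NaN (undefined).
    Missing responses are dropped pairwise.
    """
    y = np.asarray(criterion, dtype=float)
    if y.shape != (responses.n_persons,):
        raise ValueError("criterion must have one value per person")
    out: dict[str, float] = {}
    for j, item in enumerate(responses.item_ids):
        x = responses.values[:, j]
        seen = ~np.isnan(x)
        xj, yj = x[seen], y[seen]
        if xj.size < 2 or np.all(xj == xj[0]) or np.all(yj == yj[0]):
            out[item] = math.nan
            continue
        out[item] = float(np.corrcoef(xj, yj)[0, 1])
    return out
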