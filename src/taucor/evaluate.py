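"""Gene-level classification performance: sensitivity, specificity, accuracy.

A gene is called positive when its p-value falls strictly below the
significance threshold (the conventional gene-level 2.5e-6 by default).
Sensitivity is evaluated on genes carrying a true signal, specificity on genes
without one, and accuracy is their prevalence-weighted combination:

    accuracy = (n_pos_total * sensitivity + n_neg_total * specificity)
               / (n_pos_total + n_neg_total).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PerfMetrics", "performance", "round_half_up"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (0.005 -> 0.01), presentation style."""
    if math.isnan(x):
        return x
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class PerfMetrics:
    """Classification counts and derived rates at a fixed threshold.

    Fields with an empty denominator are NaN ('undefined'); counts are always
    exact.
    """

    n_pos_called: int
    n_pos_total: int
    n_neg_called: int
    n_neg_total: int

    @property
    def sensitivity(self) -> float:
        if self.n_pos_total == 0:
            return float("nan")
        return self.n_pos_called / self.n_pos_total

    @property
    def specificity(self) -> float:
        if self.n_neg_total == 0:
            return float("nan")
        return (self.n_neg_total - self.n_neg_called) / self.n_neg_total

    @property
    def accuracy(self) -> float:
        total = self.n_pos_total + self.n_neg_total
        if total == 0:
            return float("nan")
        return (self.n_pos_called + self.n_neg_total - self.n_neg_called) / total

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Presentation rounding (half-up) of the three rates."""
        return {
            "sensitivity": round_half_up(self.sensitivity, ndigits),
            "specificity": round_half_up(self.specificity, ndigits),
            "accuracy": round_half_up(self.accuracy, ndigits),
        }


def performance(pvals_pos, pvals_neg, threshold: float = 2.5e-6) -> PerfMetrics:
    """Classify p-values of true-signal and no-signal genes at a threshold.

    A call is ``p < threshold`` (strict).  Either vector may be empty, but not
    both.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    pos = np.asarray(pvals_pos, dtype=float)
    neg = np.asarray(pvals_neg, dtype=float)
    if pos.size == 0 and neg.size == 0:
        raise ValueError("no genes to classify")
    return PerfMetrics(
        n_pos_called=int(np.sum(pos < threshold)),
        n_pos_total=int(pos.size),
        n_neg_called=int(np.sum(neg < threshold)),
        n_neg_total=int(neg.size),
    )
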