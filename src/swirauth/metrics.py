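"""Classification metrics and design summary statistics.

The screening convention treats the pure (target-class) samples as the
positive class: sensitivity is the fraction of pure samples accepted,
specificity the fraction of adulterated samples rejected, accuracy the
fraction of all samples handled correctly. Percentages are reported to one
decimal with half-up rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Pure-as-positive confusion counts.

    tp: pure accepted, fn: pure rejected, tn: adulterated rejected,
    fp: adulterated accepted.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(decisions: pd.DataFrame, labels) -> ConfusionCounts:
    """Count decisions against pure/adulterated labels.

    ``decisions`` needs columns specimen_id and decision (accepted/rejected);
    ``labels`` maps specimen_id -> "pure" | "adulterated" (mapping or Series).
    """
    if len(decisions) == 0:
        raise ValueError("no decisions to score")
    labels = dict(labels)
    tp = fp = fn = tn = 0
    for sid, decision in zip(decisions["specimen_id"], decisions["decision"]):
        label = labels.get(sid)
        if label not in ("pure", "adulterated"):
            raise ValueError(f"specimen {sid!r} lacks a pure/adulterated label")
        accepted = decision == "accepted"
        if label == "pure":
            tp += accepted
            fn += not accepted
        else:
            fp += accepted
            tn += not accepted
    return ConfusionCounts(tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn))


def sensitivity(c: ConfusionCounts):
    """100 * TP / (TP + FN): percent of pure samples accepted."""
    denom = c.tp + c.fn
    if denom == 0:
        return None
    return _round_half_up(100.0 * c.tp / denom, 1)


def specificity(c: ConfusionCounts):
    """100 * TN / (FP + TN): percent of adulterated samples rejected."""
    denom = c.fp + c.tn
    if denom == 0:
        return None
    return _round_half_up(100.0 * c.tn / denom, 1)


def accuracy(c: ConfusionCounts):
    """100 * (TP + TN) / total: percent of samples handled correctly."""
    if c.total == 0:
        return None
    return _round_half_up(100.0 * (c.tp + c.tn) / c.total, 1)


@dataclass(frozen=True)
class ConcentrationSummary:
    """Descriptive statistics of a concentration design, in percent."""

    n: int
    minimum: float
    maximum: float
    mean: float
    sd: float

    def rounded(self) -> "ConcentrationSummary":
        return ConcentrationSummary(
            n=self.n,
            minimum=_round_half_up(self.minimum, 2),
            maximum=_round_half_up(self.maximum, 2),
            mean=_round_half_up(self.mean, 2),
            sd=_round_half_up(self.sd, 2),
        )


def summarize_concentrations(labels) -> ConcentrationSummary:
    """n, min, max, mean and sample standard deviation (n-1 denominator)."""
    x = np.asarray(labels, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 concentrations to summarize")
    return ConcentrationSummary(
        n=int(x.size),
        minimum=float(x.min()),
        maximum=float(x.max()),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
    )
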