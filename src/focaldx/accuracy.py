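"""Confusion tables and diagnostic test metrics with Wilson score intervals.

Sensitivity, specificity, PPV, NPV and accuracy are binomial proportions on
their own numerator/denominator; each 95% CI is the Wilson score interval
(score-test inversion, no continuity correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from scipy import stats

__all__ = [
    "ConfusionTable",
    "MetricWithCI",
    "confusion_table",
    "wilson_ci",
    "dta_summary",
    "round_half_up",
]

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    def transpose(self) -> "ConfusionTable":
        """Swap the roles of the two classes (focal <-> non-focal)."""
        return ConfusionTable(tp=self.tn, fn=self.fp, fp=self.fn, tn=self.tp)


@dataclass(frozen=True)
class MetricWithCI:
    name: str
    estimate: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.name!r}")
        if not (0 <= self.ci_low <= self.estimate <= self.ci_high <= 1):
            raise ValueError("CI must satisfy 0 <= low <= estimate <= high <= 1")


def confusion_table(predicted: Sequence[str], gold: Sequence[str]) -> ConfusionTable:
    """Tabulate paired focal/non_focal calls; 'focal' is the positive class."""
    if len(predicted) != len(gold):
        raise ValueError("predicted and gold labels differ in length")
    if not predicted:
        raise ValueError("empty label set")
    tp = fn = fp = tn = 0
    for p, g in zip(predicted, gold):
        if p not in ("focal", "non_focal") or g not in ("focal", "non_focal"):
            raise ValueError(f"labels must be focal/non_focal, got ({p!r}, {g!r})")
        if g == "focal":
            if p == "focal":
                tp += 1
            else:
                fn += 1
        else:
            if p == "focal":
                fp += 1
            else:
                tn += 1
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn)


def wilson_ci(successes: int, trials: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, without continuity
    correction.

    With z the standard-normal quantile for ``conf_level`` and p = k/n the
    interval is centred at (p + z^2/2n)/(1 + z^2/n) with half-width
    z*sqrt(p(1-p)/n + z^2/4n^2)/(1 + z^2/n).
    """
    if trials < 1:
        raise ValueError("wilson_ci requires at least one trial")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes {successes} outside [0, {trials}]")
    z = float(stats.norm.ppf(0.5 + conf_level / 2))
    n = trials
    p = successes / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    # The interval provably contains k/n; guard against last-bit rounding.
    return (min(max(0.0, centre - half), p), max(min(1.0, centre + half), p))


def _metric(name: str, k: int, n: int, conf_level: float) -> Optional[MetricWithCI]:
    if n == 0:
        return None
    lo, hi = wilson_ci(k, n, conf_level)
    return MetricWithCI(name, k / n, lo, hi, k, n)


def dta_summary(table: ConfusionTable, conf_level: float = 0.95) -> list[MetricWithCI]:
    """Sensitivity, specificity, PPV, NPV and accuracy with Wilson CIs.

    Metrics whose denominator is zero are absent from the result, never
    reported as 0.
    """
    if table.n < 1:
        raise ValueError("empty confusion table")
    candidates = [
        _metric("sensitivity", table.tp, table.tp + table.fn, conf_level),
        _metric("specificity", table.tn, table.tn + table.fp, conf_level),
        _metric("ppv", table.tp, table.tp + table.fp, conf_level),
        _metric("npv", table.tn, table.tn + table.fn, conf_level),
        _metric("accuracy", table.tp + table.tn, table.n, conf_level),
    ]
    return [m for m in candidates if m is not None]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding matching clinical-report conventions (0.005 -> 0.01)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
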