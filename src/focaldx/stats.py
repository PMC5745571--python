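"""Group comparisons and severity-trend models.

Mann-Whitney U compares score distributions between gold-standard classes;
the p-value is exact (full enumeration) for small tie-free samples
(n1*n2 <= 400) and otherwise uses the normal approximation with
tie-corrected variance and continuity correction.  Severity-versus-score
associations are ordinary least-squares fits with a two-sided t-test on the
slope (n-2 degrees of freedom); pairs with missing values are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["GroupTestResult", "TrendResult", "mann_whitney_u", "linear_trend"]

EXACT_ENUMERATION_LIMIT = 400  # n1*n2 above this (or any ties) -> normal approx


@dataclass(frozen=True)
class GroupTestResult:
    u_statistic: float  # U of the first sample: pairs where x outranks y
    p_value: float
    n1: int
    n2: int
    median1: float
    iqr1: tuple[float, float]
    median2: float
    iqr2: tuple[float, float]
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.u_statistic <= self.n1 * self.n2:
            raise ValueError("U outside [0, n1*n2]")


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    p_value: float
    stderr: float
    n: int
    n_dropped: int


def _summary(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    return float(np.median(x)), (float(np.percentile(x, 25)), float(np.percentile(x, 75)))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> GroupTestResult:
    """Two-sided Mann-Whitney U test of x versus y.

    U counts (x, y) pairs where x exceeds y, ties at half weight, so
    U/(n1*n2) is the AUC of the pooled scores with group membership as the
    label.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = not has_ties and len(x) * len(y) <= EXACT_ENUMERATION_LIMIT
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    m1, q1 = _summary(x)
    m2, q2 = _summary(y)
    return GroupTestResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=len(x),
        n2=len(y),
        median1=m1,
        iqr1=q1,
        median2=m2,
        iqr2=q2,
        method="exact" if exact else "asymptotic",
    )


def linear_trend(predictor: Sequence, response: Sequence) -> TrendResult:
    """OLS slope of response on predictor with a two-sided t-test.

    Missing values (None/NaN) are dropped pairwise and counted.
    """
    pred = np.array([math.nan if v is None else float(v) for v in predictor])
    resp = np.array([math.nan if v is None else float(v) for v in response])
    if len(pred) != len(resp):
        raise ValueError("predictor and response differ in length")
    keep = ~(np.isnan(pred) | np.isnan(resp))
    n_dropped = int((~keep).sum())
    pred, resp = pred[keep], resp[keep]
    if len(pred) < 3:
        raise ValueError("linear trend needs at least 3 complete pairs")
    if np.ptp(pred) == 0:
        raise ValueError("predictor has zero variance")
    fit = stats.linregress(pred, resp)
    # Constant response: slope 0 exactly, no evidence of trend.
    p = 1.0 if np.ptp(resp) == 0 else float(fit.pvalue)
    return TrendResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=p,
        stderr=float(fit.stderr),
        n=len(pred),
        n_dropped=n_dropped,
    )
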