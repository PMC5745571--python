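"""Empirical ROC analysis with bootstrap inference.

The ROC threshold grid is the set of midpoints between consecutive sorted
unique scores, bracketed by -inf/+inf sentinels; a score strictly above the
threshold reads as positive.  The AUC of this empirical curve equals the
concordant-pair fraction (tied pairs count one half).  Interval estimates
use a stratified nonparametric bootstrap — positives and negatives resampled
independently, preserving the class sizes, so no replicate degenerates to a
single class — with percentile CIs.  The accuracy-maximising cut-off is
searched on the same midpoint grid, ties broken toward the lowest candidate.
The tracer-superiority test resamples two independent cohorts and refers the
AUC difference, standardised by its bootstrap SD, to the standard normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RocResult",
    "CutoffResult",
    "AucComparison",
    "roc_curve",
    "bootstrap_auc",
    "optimal_cutoff",
    "compare_auc_unpaired",
]

_POSITIVE = {1, True, "focal"}
_NEGATIVE = {0, False, "non_focal"}


@dataclass(frozen=True)
class RocResult:
    thresholds: tuple[float, ...]
    sens_points: tuple[float, ...]
    spec_points: tuple[float, ...]
    auc: float
    n_pos: int
    n_neg: int
    auc_ci: Optional[tuple[float, float]] = None
    replicates: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.auc_ci is not None and not (
            self.auc_ci[0] - 1e-12 <= self.auc <= self.auc_ci[1] + 1e-12
        ):
            raise ValueError("AUC must lie within its CI")


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    accuracy_at_cutoff: float
    cutoff_ci: Optional[tuple[float, float]] = None
    replicates: Optional[int] = None
    seed: Optional[int] = None


@dataclass(frozen=True)
class AucComparison:
    auc1: float
    auc2: float
    difference: float
    z_statistic: float
    p_value: float
    alternative: str
    replicates: int
    seed: int
    degenerate_variance: bool = False


def _split_classes(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    pos_mask = np.array([l in _POSITIVE for l in labels])
    neg_mask = np.array([l in _NEGATIVE for l in labels])
    if not np.all(pos_mask | neg_mask):
        raise ValueError("labels must be focal/non_focal (or 1/0)")
    pos, neg = scores[pos_mask], scores[neg_mask]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    return pos, neg


def _threshold_grid(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _auc_from_pairs(pos: np.ndarray, neg: np.ndarray) -> float:
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (len(pos) * len(neg))


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC points and AUC (no bootstrap CI)."""
    pos, neg = _split_classes(scores, labels)
    thr = _threshold_grid(np.concatenate([pos, neg]))
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    sens = 1 - np.searchsorted(pos_sorted, thr, side="right") / len(pos)
    spec = np.searchsorted(neg_sorted, thr, side="right") / len(neg)
    auc = _auc_from_pairs(pos, neg)
    return RocResult(
        thresholds=tuple(thr.tolist()),
        sens_points=tuple(sens.tolist()),
        spec_points=tuple(spec.tolist()),
        auc=float(auc),
        n_pos=len(pos),
        n_neg=len(neg),
    )


def _resample_indices(rng: np.random.Generator, n: int, replicates: int) -> np.ndarray:
    return rng.integers(0, n, size=(replicates, n))


def _batch_auc(pos_mat: np.ndarray, neg_mat: np.ndarray, chunk: int = 512) -> np.ndarray:
    b, n_pos = pos_mat.shape
    n_neg = neg_mat.shape[1]
    out = np.empty(b)
    for start in range(0, b, chunk):
        p = pos_mat[start : start + chunk, :, None]
        q = neg_mat[start : start + chunk, None, :]
        greater = (p > q).sum(axis=(1, 2))
        ties = (p == q).sum(axis=(1, 2))
        out[start : start + chunk] = (greater + 0.5 * ties) / (n_pos * n_neg)
    return out


def bootstrap_auc(
    scores,
    labels,
    replicates: int = 10_000,
    seed: int = 0,
    conf_level: float = 0.95,
    stratified: bool = True,
) -> RocResult:
    """ROC with a stratified percentile-bootstrap CI on the AUC.

    Deterministic given ``seed``; replicates with a single class cannot
    occur under stratified resampling.
    """
    base = roc_curve(scores, labels)
    pos, neg = _split_classes(scores, labels)
    rng = np.random.default_rng(seed)
    if stratified:
        pos_mat = pos[_resample_indices(rng, len(pos), replicates)]
        neg_mat = neg[_resample_indices(rng, len(neg), replicates)]
        aucs = _batch_auc(pos_mat, neg_mat)
    else:
        scores_arr = np.concatenate([pos, neg])
        lab_arr = np.concatenate([np.ones(len(pos), bool), np.zeros(len(neg), bool)])
        aucs = np.empty(replicates)
        n = len(scores_arr)
        for i in range(replicates):
            idx = rng.integers(0, n, size=n)
            s, l = scores_arr[idx], lab_arr[idx]
            if l.all() or not l.any():  # resampled a single class; AUC undefined
                aucs[i] = np.nan
                continue
            aucs[i] = _auc_from_pairs(s[l], s[~l])
        aucs = aucs[~np.isnan(aucs)]
    alpha = 1 - conf_level
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return RocResult(
        thresholds=base.thresholds,
        sens_points=base.sens_points,
        spec_points=base.spec_points,
        auc=base.auc,
        n_pos=base.n_pos,
        n_neg=base.n_neg,
        auc_ci=(float(min(lo, base.auc)), float(max(hi, base.auc))),
        replicates=replicates,
        seed=seed,
    )


def _best_cutoff(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    thr = _threshold_grid(np.concatenate([pos, neg]))
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    tp = len(pos) - np.searchsorted(pos_sorted, thr, side="right")
    tn = np.searchsorted(neg_sorted, thr, side="right")
    acc = (tp + tn) / (len(pos) + len(neg))
    best = int(np.argmax(acc))  # first maximum = lowest candidate
    return float(thr[best]), float(acc[best])


def optimal_cutoff(
    scores,
    labels,
    replicates: int = 10_000,
    seed: int = 0,
    conf_level: float = 0.95,
) -> CutoffResult:
    """Accuracy-maximising cut-off with a stratified-bootstrap percentile CI.

    The point estimate is the lowest midpoint-grid threshold maximising
    (tp+tn)/n on the original sample; each bootstrap replicate repeats the
    search on its own resampled grid.
    """
    pos, neg = _split_classes(scores, labels)
    cutoff, acc = _best_cutoff(pos, neg)
    rng = np.random.default_rng(seed)
    boot = np.empty(replicates)
    for i in range(replicates):
        p = pos[rng.integers(0, len(pos), size=len(pos))]
        q = neg[rng.integers(0, len(neg), size=len(neg))]
        boot[i], _ = _best_cutoff(p, q)
    alpha = 1 - conf_level
    # Replicate cutoffs may be +/-inf sentinels; avoid interpolating across them.
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2], method="nearest")
    return CutoffResult(
        cutoff=cutoff,
        accuracy_at_cutoff=acc,
        cutoff_ci=(float(lo), float(hi)),
        replicates=replicates,
        seed=seed,
    )


def compare_auc_unpaired(
    scores1,
    labels1,
    scores2,
    labels2,
    replicates: int = 10_000,
    seed: int = 0,
    alternative: str = "two_sided",
) -> AucComparison:
    """Non-paired bootstrap test of an AUC difference between two cohorts.

    Each cohort is resampled independently (stratified) per replicate;
    D = (AUC1 - AUC2) / sd_boot(difference) is referred to the standard
    normal.  ``alternative='greater'`` tests superiority of cohort 1.
    """
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pos1, neg1 = _split_classes(scores1, labels1)
    pos2, neg2 = _split_classes(scores2, labels2)
    auc1 = _auc_from_pairs(pos1, neg1)
    auc2 = _auc_from_pairs(pos2, neg2)
    rng = np.random.default_rng(seed)
    a1 = _batch_auc(
        pos1[_resample_indices(rng, len(pos1), replicates)],
        neg1[_resample_indices(rng, len(neg1), replicates)],
    )
    a2 = _batch_auc(
        pos2[_resample_indices(rng, len(pos2), replicates)],
        neg2[_resample_indices(rng, len(neg2), replicates)],
    )
    diffs = a1 - a2
    sd = float(diffs.std(ddof=1))
    diff = float(auc1 - auc2)
    degenerate = sd == 0.0
    if degenerate:
        if diff == 0.0:
            z, p = 0.0, 1.0
        else:
            z = math.inf if diff > 0 else -math.inf
            p = 1.0 / replicates  # resolution floor; flagged as degenerate
    else:
        z = diff / sd
        if alternative == "two_sided":
            p = 2 * stats.norm.sf(abs(z))
        elif alternative == "greater":
            p = stats.norm.sf(z)
        else:
            p = stats.norm.cdf(z)
    return AucComparison(
        auc1=float(auc1),
        auc2=float(auc2),
        difference=diff,
        z_statistic=float(z),
        p_value=float(min(p, 1.0)),
        alternative=alternative,
        replicates=replicates,
        seed=seed,
        degenerate_variance=degenerate,
    )
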