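"""Blinded dual-reader protocol: disagreement flags, adjudication, kappa, ICC.

Two readers measure every scan independently.  A pair of reads is flagged
for third-reader adjudication when any of four predefined rules fires:

* ``suv_gt_10pct`` — a matched SUV_max measurement differs by more than 10%
  of the two-reader mean (the symmetric relative difference);
* ``ratio_gt_0p2`` — the two time-maximum SUV ratios differ by more than 0.2;
* ``conclusion_differs`` — the ratio classifications at the predefined
  cut-off of 1.45 disagree (DOPA only);
* ``visual_differs`` — the visual calls disagree.

Agreement statistics are Cohen's kappa for categorical reads (large-sample
delta-method standard error, normal-approximation CI, estimate clamped to
[-1, 1]) and the intraclass correlation for continuous reads — two-way
random effects, single rater, absolute agreement (ICC(2,1)) by default, with
the consistency form ICC(3,1) also available; CIs come from the exact
F-distribution bounds of the two-way mean squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import ScanReading
from .quantification import classify_by_cutoff, compute_suv_ratio

__all__ = [
    "DisagreementFlag",
    "AgreementResult",
    "PairingError",
    "flag_disagreements",
    "adjudicate",
    "cohen_kappa",
    "icc",
]

PREDEFINED_RATIO_CUTOFF = 1.45
DISAGREEMENT_RULES = ("suv_gt_10pct", "ratio_gt_0p2", "conclusion_differs", "visual_differs")


class PairingError(ValueError):
    """The two readers' reads do not cover the same patients/timepoints."""


@dataclass(frozen=True)
class DisagreementFlag:
    patient_id: str
    tracer: str
    rules_triggered: tuple[str, ...]
    resolved_by: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.rules_triggered:
            raise ValueError("a disagreement flag needs at least one rule")
        unknown = set(self.rules_triggered) - set(DISAGREEMENT_RULES)
        if unknown:
            raise ValueError(f"unknown rules {sorted(unknown)}")


@dataclass(frozen=True)
class AgreementResult:
    statistic: str  # "kappa" or "icc"
    estimate: float
    ci_low: float
    ci_high: float
    n_subjects: int
    undefined: bool = False

    def __post_init__(self) -> None:
        if not self.undefined and not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def _series_by_key(reads: Sequence[ScanReading]) -> dict[tuple[str, str], list[ScanReading]]:
    out: dict[tuple[str, str], list[ScanReading]] = {}
    for r in reads:
        out.setdefault((r.patient_id, r.tracer), []).append(r)
    for rows in out.values():
        rows.sort(key=lambda r: r.timepoint_min)
    return out


def _series_visual(rows: Sequence[ScanReading]) -> str:
    return rows[0].visual_call  # one call per scan; rows sorted by timepoint


def flag_disagreements(
    readsA: Sequence[ScanReading],
    readsB: Sequence[ScanReading],
    predefined_cutoff: float = PREDEFINED_RATIO_CUTOFF,
    suv_rel_tol: float = 0.10,
    ratio_tol: float = 0.2,
) -> list[DisagreementFlag]:
    """Apply the four disagreement rules to every matched patient/tracer series.

    The 10% rule is evaluated against every matched timepoint's lesion and
    reference SUV; its denominator is the two-reader mean, so the outcome is
    symmetric in reader order.
    """
    a = _series_by_key(readsA)
    b = _series_by_key(readsB)
    if set(a) != set(b):
        raise PairingError(
            f"reader series differ: only-A={sorted(set(a) - set(b))}, "
            f"only-B={sorted(set(b) - set(a))}"
        )
    flags = []
    for key in sorted(a):
        rows_a, rows_b = a[key], b[key]
        times_a = [r.timepoint_min for r in rows_a]
        times_b = [r.timepoint_min for r in rows_b]
        if times_a != times_b:
            raise PairingError(f"series {key}: timepoints differ ({times_a} vs {times_b})")
        rules = []
        pairs = [
            (ra.suv_max_lesion, rb.suv_max_lesion) for ra, rb in zip(rows_a, rows_b)
        ] + [(ra.suv_max_reference, rb.suv_max_reference) for ra, rb in zip(rows_a, rows_b)]
        if any(abs(x - y) / ((x + y) / 2) > suv_rel_tol for x, y in pairs):
            rules.append("suv_gt_10pct")
        score_a = compute_suv_ratio(rows_a).score
        score_b = compute_suv_ratio(rows_b).score
        if abs(score_a - score_b) > ratio_tol:
            rules.append("ratio_gt_0p2")
        if key[1] == "DOPA" and classify_by_cutoff(score_a, predefined_cutoff) != classify_by_cutoff(
            score_b, predefined_cutoff
        ):
            rules.append("conclusion_differs")
        if _series_visual(rows_a) != _series_visual(rows_b):
            rules.append("visual_differs")
        if rules:
            flags.append(DisagreementFlag(key[0], key[1], tuple(rules)))
    return flags


def adjudicate(
    readsA: Sequence[ScanReading],
    readsB: Sequence[ScanReading],
    readsC: Sequence[ScanReading],
    flags: Sequence[DisagreementFlag],
    consensus_reader_id: str = "consensus",
) -> tuple[list[ScanReading], list[DisagreementFlag]]:
    """Build the post-adjudication consensus read set.

    Flagged series take the third reader's values wholesale (``resolved_by``
    records the adjudicator); unflagged series average the two readers' SUVs
    and keep their shared visual call.
    """
    a = _series_by_key(readsA)
    b = _series_by_key(readsB)
    c = _series_by_key(readsC)
    flagged = {(f.patient_id, f.tracer) for f in flags}
    missing = flagged - set(c)
    if missing:
        raise PairingError(f"no adjudicator reads for flagged series {sorted(missing)}")
    consensus: list[ScanReading] = []
    for key in sorted(a):
        source = c[key] if key in flagged else None
        if source is not None:
            for r in source:
                consensus.append(replace(r, reader_id=consensus_reader_id))
        else:
            for ra, rb in zip(a[key], b[key]):
                consensus.append(
                    replace(
                        ra,
                        reader_id=consensus_reader_id,
                        suv_max_lesion=(ra.suv_max_lesion + rb.suv_max_lesion) / 2,
                        suv_max_reference=(ra.suv_max_reference + rb.suv_max_reference) / 2,
                    )
                )
    resolved = [
        replace(f, resolved_by=(c[(f.patient_id, f.tracer)][0].reader_id)) for f in flags
    ]
    return consensus, resolved


def cohen_kappa(
    labelsA: Sequence, labelsB: Sequence, conf_level: float = 0.95
) -> AgreementResult:
    """Cohen's chance-corrected agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e) with the asymptotic delta-method
    variance of the full contingency table; the CI is the normal
    approximation, clamped to [-1, 1].  Both raters constant and equal
    (p_e = 1) yields an undefined result rather than an error.
    """
    if len(labelsA) != len(labelsB):
        raise PairingError("label sequences differ in length")
    n = len(labelsA)
    if n < 2:
        raise ValueError("kappa needs at least 2 subjects")
    cats = sorted(set(labelsA) | set(labelsB), key=str)
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((k, k))
    for la, lb in zip(labelsA, labelsB):
        table[idx[la], idx[lb]] += 1
    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    if 1 - p_e < 1e-12:
        return AgreementResult("kappa", math.nan, math.nan, math.nan, n, undefined=True)
    kappa = (p_o - p_e) / (1 - p_e)

    # Fleiss-Cohen-Everitt large-sample variance.
    a = sum(
        p[i, i] * ((1 - p_e) - (col[i] + row[i]) * (1 - p_o)) ** 2 for i in range(k)
    )
    b = (1 - p_o) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(k) for j in range(k) if i != j
    )
    c = (p_o * p_e - 2 * p_e + p_o) ** 2
    var = (a + b - c) / (n * (1 - p_e) ** 4)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + conf_level / 2)
    est = min(1.0, max(-1.0, kappa))
    lo = min(1.0, max(-1.0, kappa - z * se))
    hi = min(1.0, max(-1.0, kappa + z * se))
    return AgreementResult("kappa", est, min(lo, est), max(hi, est), n)


def _two_way_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((values - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(
    values, conf_level: float = 0.95, form: str = "absolute_agreement"
) -> AgreementResult:
    """Intraclass correlation of a subjects x raters numeric layout.

    ``absolute_agreement`` is ICC(2,1): two-way random effects, single
    rater, absolute agreement — systematic shifts between raters lower the
    coefficient.  ``consistency`` is ICC(3,1), which discounts a fixed
    rater offset.  CIs follow the F-distribution bounds of the two-way
    ANOVA mean squares.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("values must be a subjects x raters (>=2) array")
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if np.ptp(x) == 0:
        return AgreementResult("icc", math.nan, math.nan, math.nan, n, undefined=True)
    msr, msc, mse = _two_way_mean_squares(x)
    alpha = 1 - conf_level

    if form == "consistency":
        est = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:  # raters perfectly consistent; F ratio degenerates
            lo = hi = 1.0
        else:
            f_obs = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    elif form == "absolute_agreement":
        est = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        # Satterthwaite df for the denominator's MS combination.
        a = (k * est) / (n * (1 - est)) if est < 1 else 0.0
        b = 1 + (k * est * (n - 1)) / (n * (1 - est)) if est < 1 else 1.0
        denom = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = ((a * msc + b * mse) ** 2 / denom) if denom > 0 else (n - 1) * (k - 1)
        f_lower = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_upper = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_lower * mse) / (
            f_lower * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_upper * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_upper * msr
        )
    else:
        raise ValueError(f"unknown ICC form {form!r}")

    est_c = min(1.0, max(-1.0, est))
    lo_c = min(min(1.0, max(-1.0, lo)), est_c)
    hi_c = max(min(1.0, max(-1.0, hi)), est_c)
    return AgreementResult("icc", est_c, lo_c, hi_c, n)
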