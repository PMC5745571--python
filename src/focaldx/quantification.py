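"""Per-patient tracer scores from serial SUV_max readings.

The DOPA score is the lesion-to-reference SUV_max ratio, computed per
timepoint and maximised over the acquisition series; the DOTANOC score is
the absolute lesion SUV_max (g/ml), likewise maximised over timepoints.
Ties between timepoints break toward the earliest acquisition.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .cohort import Cohort, PatientRecord, ScanReading

__all__ = [
    "SuvScore",
    "MissingDataError",
    "compute_suv_ratio",
    "compute_suv_max",
    "score_readings",
    "classify_by_cutoff",
    "localization_concordance",
    "write_scores",
]


class MissingDataError(ValueError):
    """No usable timepoint for the requested score."""


@dataclass(frozen=True)
class SuvScore:
    patient_id: str
    tracer: str
    reader_id: str
    score: float  # dimensionless ratio (DOPA) or g/ml (DOTANOC)
    timepoint_of_max: float
    predicted_location: Optional[str] = None

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ValueError(f"score must be positive, got {self.score}")


def _series_meta(readings: Sequence[ScanReading]) -> tuple[str, str, str]:
    keys = {(r.patient_id, r.tracer, r.reader_id) for r in readings}
    if len(keys) != 1:
        raise ValueError(f"readings span multiple patient/tracer/reader series: {sorted(keys)}")
    return next(iter(keys))


def _predicted_location(readings: Sequence[ScanReading]) -> Optional[str]:
    # One location per score: the modal non-null visual location, earliest-
    # timepoint first on ties.
    locs = [r.visual_location for r in sorted(readings, key=lambda r: r.timepoint_min)
            if r.visual_location is not None]
    if not locs:
        return None
    counts = Counter(locs)
    best = max(counts.values())
    for loc in locs:
        if counts[loc] == best:
            return loc
    return None  # pragma: no cover


def compute_suv_ratio(readings: Sequence[ScanReading]) -> SuvScore:
    """Time-maximum lesion/reference SUV_max ratio for one series."""
    if not readings:
        raise MissingDataError("empty reading series")
    pid, tracer, reader = _series_meta(readings)
    best_t, best_ratio = None, None
    for r in sorted(readings, key=lambda r: r.timepoint_min):
        ratio = r.suv_max_lesion / r.suv_max_reference
        if best_ratio is None or ratio > best_ratio:
            best_t, best_ratio = r.timepoint_min, ratio
    return SuvScore(
        patient_id=pid,
        tracer=tracer,
        reader_id=reader,
        score=best_ratio,
        timepoint_of_max=best_t,
        predicted_location=_predicted_location(readings),
    )


def compute_suv_max(readings: Sequence[ScanReading]) -> SuvScore:
    """Time-maximum absolute lesion SUV_max (g/ml) for one series."""
    if not readings:
        raise MissingDataError("empty reading series")
    pid, tracer, reader = _series_meta(readings)
    best_t, best_suv = None, None
    for r in sorted(readings, key=lambda r: r.timepoint_min):
        if best_suv is None or r.suv_max_lesion > best_suv:
            best_t, best_suv = r.timepoint_min, r.suv_max_lesion
    return SuvScore(
        patient_id=pid,
        tracer=tracer,
        reader_id=reader,
        score=best_suv,
        timepoint_of_max=best_t,
        predicted_location=_predicted_location(readings),
    )


def score_readings(
    readings: Iterable[ScanReading], tracer: str, reader_id: str
) -> dict[str, SuvScore]:
    """Score every patient series for one tracer/reader.

    DOPA uses the SUV_max ratio; DOTANOC the absolute SUV_max.
    """
    series: dict[str, list[ScanReading]] = {}
    for r in readings:
        if r.tracer == tracer and r.reader_id == reader_id:
            series.setdefault(r.patient_id, []).append(r)
    scorer = compute_suv_ratio if tracer == "DOPA" else compute_suv_max
    return {pid: scorer(rows) for pid, rows in series.items()}


def classify_by_cutoff(score: float, cutoff: float) -> str:
    """Strictly-above-cutoff rule: score > cutoff reads as focal."""
    if score <= 0 or cutoff <= 0:
        raise ValueError("score and cutoff must be positive")
    return "focal" if score > cutoff else "non_focal"


def localization_concordance(
    scores: dict[str, SuvScore], patients: Iterable[PatientRecord]
) -> tuple[Optional[float], int, int, dict[str, bool]]:
    """Fraction of histology-focal patients whose predicted location matches surgery.

    Only histology-focal patients with a predicted location are eligible.
    An ectopic surgical lesion counts as a match only when predicted ectopic.
    Returns ``(fraction, matches, eligible, per_patient)``; the fraction is
    None (absent, not 0) when no patient is eligible.
    """
    per_patient: dict[str, bool] = {}
    for p in patients:
        if not (p.surgery and p.histology == "focal"):
            continue
        sc = scores.get(p.patient_id)
        if sc is None or sc.predicted_location is None or p.lesion_location_surgical is None:
            continue
        per_patient[p.patient_id] = sc.predicted_location == p.lesion_location_surgical
    eligible = len(per_patient)
    matches = sum(per_patient.values())
    fraction = matches / eligible if eligible else None
    return fraction, matches, eligible, per_patient


def write_scores(scores: Iterable[SuvScore], path: str | Path) -> None:
    buf = io.StringIO()
    buf.write("patient_id,tracer,reader_id,score,timepoint_of_max,predicted_location\n")
    for s in scores:
        loc = s.predicted_location or ""
        buf.write(
            f"{s.patient_id},{s.tracer},{s.reader_id},{s.score!r},{s.timepoint_of_max:g},{loc}\n"
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
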