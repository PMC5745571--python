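"""Domain types and CSV readers/writers for patient cohorts and scan readings.

A cohort is exchanged as three UTF-8 CSV files with "." as decimal separator:

``patients.csv``
    patient_id, sex, age_at_scan_months, surgery, histology,
    lesion_location_surgical, lowest_glucose, max_glucose_infusion,
    insulin, proinsulin, c_peptide, insulin_to_glucose

``genetics.csv`` (one row per finding)
    patient_id, gene, inheritance, pathogenicity

``readings.csv``
    patient_id, tracer, reader_id, timepoint_min, suv_max_lesion,
    suv_max_reference, reference_region, visual_call, visual_location

Optional fields are empty cells, never sentinel numbers.  ``read_cohort``
followed by ``write_cohort`` is the identity on the canonical dialect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "GeneticFinding",
    "SeverityPanel",
    "PatientRecord",
    "ScanReading",
    "Cohort",
    "CohortSchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "DEFAULT_TIMEPOINTS",
]

SEXES = frozenset({"female", "male"})
HISTOLOGIES = frozenset({"focal", "diffuse", "atypical", "normal", "none"})
GENES = frozenset({"ABCC8", "KCNJ11", "GLUD1", "HNF4A", "HNF1A", "GCK", "other"})
INHERITANCES = frozenset(
    {"paternal", "maternal", "de_novo", "compound_heterozygous", "homozygous", "unknown"}
)
PATHOGENICITIES = frozenset({"pathogenic", "uncertain"})
TRACERS = frozenset({"DOPA", "DOTANOC"})
REGIONS = frozenset({"head", "body", "tail", "ectopic", "diffuse"})
REFERENCE_REGIONS = frozenset({"pancreas_body", "pancreas_head", "spleen", "liver", "none"})
VISUAL_CALLS = frozenset({"focal", "non_focal"})

#: Acquisition timepoints (minutes post-injection) accepted by default.
DEFAULT_TIMEPOINTS = frozenset({10.0, 30.0, 45.0, 60.0})


class CohortSchemaError(ValueError):
    """A table is missing a required column or has an unreadable layout."""


class CohortValidationError(ValueError):
    """A row violates a domain invariant; the message carries its location."""


@dataclass(frozen=True)
class GeneticFinding:
    gene: str
    inheritance: str = "unknown"
    pathogenicity: str = "pathogenic"

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise CohortValidationError(f"unknown gene {self.gene!r}")
        if self.inheritance not in INHERITANCES:
            raise CohortValidationError(f"unknown inheritance {self.inheritance!r}")
        if self.pathogenicity not in PATHOGENICITIES:
            raise CohortValidationError(f"unknown pathogenicity {self.pathogenicity!r}")


@dataclass(frozen=True)
class SeverityPanel:
    """Disease-severity biomarkers; all optional, all non-negative when present.

    Units: glucose mmol/L, glucose infusion mg/kg/min, insulin / proinsulin /
    C-peptide pmol/L, insulin-to-glucose pmol/mmol.
    """

    lowest_glucose: Optional[float] = None
    max_glucose_infusion: Optional[float] = None
    insulin: Optional[float] = None
    proinsulin: Optional[float] = None
    c_peptide: Optional[float] = None
    insulin_to_glucose: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "lowest_glucose",
            "max_glucose_infusion",
            "insulin",
            "proinsulin",
            "c_peptide",
            "insulin_to_glucose",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise CohortValidationError(f"severity field {name} negative: {v}")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str
    age_at_scan_months: float
    surgery: bool
    histology: str = "none"
    genetics: tuple[GeneticFinding, ...] = ()
    lesion_location_surgical: Optional[str] = None
    severity: SeverityPanel = field(default_factory=SeverityPanel)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortValidationError("empty patient_id")
        if self.sex not in SEXES:
            raise CohortValidationError(f"patient {self.patient_id}: unknown sex {self.sex!r}")
        if self.age_at_scan_months < 0:
            raise CohortValidationError(f"patient {self.patient_id}: negative age")
        if self.histology not in HISTOLOGIES:
            raise CohortValidationError(
                f"patient {self.patient_id}: unknown histology {self.histology!r}"
            )
        # Histology exists exactly when tissue was resected.
        if self.surgery and self.histology == "none":
            raise CohortValidationError(
                f"patient {self.patient_id}: surgery without a histology report"
            )
        if not self.surgery and self.histology != "none":
            raise CohortValidationError(
                f"patient {self.patient_id}: histology {self.histology!r} without surgery"
            )
        if self.lesion_location_surgical is not None and self.lesion_location_surgical not in REGIONS:
            raise CohortValidationError(
                f"patient {self.patient_id}: unknown region {self.lesion_location_surgical!r}"
            )


@dataclass(frozen=True)
class ScanReading:
    """One reader's SUV_max measurements and visual call for one acquisition."""

    patient_id: str
    tracer: str
    reader_id: str
    timepoint_min: float
    suv_max_lesion: float  # g/ml
    suv_max_reference: float  # g/ml
    reference_region: str = "pancreas_body"
    visual_call: str = "non_focal"
    visual_location: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tracer not in TRACERS:
            raise CohortValidationError(
                f"reading {self.patient_id}: unknown tracer {self.tracer!r}"
            )
        if self.timepoint_min <= 0:
            raise CohortValidationError(
                f"reading {self.patient_id}: non-positive timepoint {self.timepoint_min}"
            )
        if self.suv_max_lesion <= 0 or self.suv_max_reference <= 0:
            raise CohortValidationError(
                f"reading {self.patient_id}/{self.tracer}/{self.reader_id}"
                f"@{self.timepoint_min}: SUV_max must be strictly positive"
            )
        if self.reference_region not in REFERENCE_REGIONS:
            raise CohortValidationError(
                f"reading {self.patient_id}: unknown reference region {self.reference_region!r}"
            )
        if self.visual_call not in VISUAL_CALLS:
            raise CohortValidationError(
                f"reading {self.patient_id}: unknown visual call {self.visual_call!r}"
            )
        if self.visual_location is not None and self.visual_location not in REGIONS:
            raise CohortValidationError(
                f"reading {self.patient_id}: unknown visual location {self.visual_location!r}"
            )

    @property
    def key(self) -> tuple[str, str, str, float]:
        return (self.patient_id, self.tracer, self.reader_id, self.timepoint_min)


@dataclass
class Cohort:
    patients: list[PatientRecord]
    readings: list[ScanReading]

    def validate(self, allowed_timepoints: Iterable[float] = DEFAULT_TIMEPOINTS) -> "Cohort":
        allowed = frozenset(float(t) for t in allowed_timepoints)
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_id(s): {dupes}")
        known = set(ids)
        seen_keys: set[tuple] = set()
        for i, r in enumerate(self.readings):
            if r.patient_id not in known:
                raise CohortValidationError(f"readings row {i}: unknown patient {r.patient_id!r}")
            if r.timepoint_min not in allowed:
                raise CohortValidationError(
                    f"readings row {i}: timepoint {r.timepoint_min} not in allowed set "
                    f"{sorted(allowed)}"
                )
            if r.key in seen_keys:
                raise CohortValidationError(f"readings row {i}: duplicate reading key {r.key}")
            seen_keys.add(r.key)
        return self

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def readings_for(
        self,
        tracer: Optional[str] = None,
        reader_id: Optional[str] = None,
        patient_id: Optional[str] = None,
    ) -> list[ScanReading]:
        out = self.readings
        if tracer is not None:
            out = [r for r in out if r.tracer == tracer]
        if reader_id is not None:
            out = [r for r in out if r.reader_id == reader_id]
        if patient_id is not None:
            out = [r for r in out if r.patient_id == patient_id]
        return out

    def scanned_patient_ids(self, tracer: str) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.readings:
            if r.tracer == tracer:
                seen.setdefault(r.patient_id, None)
        return list(seen)


PATIENT_COLUMNS = [
    "patient_id",
    "sex",
    "age_at_scan_months",
    "surgery",
    "histology",
    "lesion_location_surgical",
    "lowest_glucose",
    "max_glucose_infusion",
    "insulin",
    "proinsulin",
    "c_peptide",
    "insulin_to_glucose",
]
GENETICS_COLUMNS = ["patient_id", "gene", "inheritance", "pathogenicity"]
READING_COLUMNS = [
    "patient_id",
    "tracer",
    "reader_id",
    "timepoint_min",
    "suv_max_lesion",
    "suv_max_reference",
    "reference_region",
    "visual_call",
    "visual_location",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{table}: missing required column(s) {missing}")


def _opt_str(cell) -> Optional[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    s = str(cell).strip()
    return s or None


def _opt_float(cell, table: str, row: int, col: str) -> Optional[float]:
    s = _opt_str(cell)
    if s is None:
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise CohortValidationError(f"{table} row {row}: bad numeric {col}={s!r}") from exc


def _req_float(cell, table: str, row: int, col: str) -> float:
    v = _opt_float(cell, table, row, col)
    if v is None:
        raise CohortValidationError(f"{table} row {row}: missing required value {col}")
    return v


def _parse_bool(cell, table: str, row: int) -> bool:
    s = (_opt_str(cell) or "").lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise CohortValidationError(f"{table} row {row}: bad boolean surgery={s!r}")


def read_cohort(
    patients_path: str | Path,
    genetics_path: str | Path,
    readings_path: str | Path,
    allowed_timepoints: Iterable[float] = DEFAULT_TIMEPOINTS,
) -> Cohort:
    """Load and validate a cohort from the three canonical CSV tables.

    Raises :class:`CohortSchemaError` for missing columns and
    :class:`CohortValidationError` (with the offending row index) for value
    errors such as non-positive SUVs or duplicate reading keys.
    """
    pt = pd.read_csv(patients_path, dtype=str)
    gn = pd.read_csv(genetics_path, dtype=str)
    rd = pd.read_csv(readings_path, dtype=str)
    _require_columns(pt, PATIENT_COLUMNS, "patients")
    _require_columns(gn, GENETICS_COLUMNS, "genetics")
    _require_columns(rd, READING_COLUMNS, "readings")

    findings: dict[str, list[GeneticFinding]] = {}
    for i, row in gn.iterrows():
        pid = _opt_str(row["patient_id"])
        if pid is None:
            raise CohortValidationError(f"genetics row {i}: missing patient_id")
        try:
            findings.setdefault(pid, []).append(
                GeneticFinding(
                    gene=_opt_str(row["gene"]) or "",
                    inheritance=_opt_str(row["inheritance"]) or "unknown",
                    pathogenicity=_opt_str(row["pathogenicity"]) or "",
                )
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"genetics row {i}: {exc}") from exc

    patients = []
    for i, row in pt.iterrows():
        pid = _opt_str(row["patient_id"])
        if pid is None:
            raise CohortValidationError(f"patients row {i}: missing patient_id")
        try:
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    sex=_opt_str(row["sex"]) or "",
                    age_at_scan_months=_req_float(row["age_at_scan_months"], "patients", i, "age_at_scan_months"),
                    surgery=_parse_bool(row["surgery"], "patients", i),
                    histology=_opt_str(row["histology"]) or "none",
                    genetics=tuple(findings.get(pid, ())),
                    lesion_location_surgical=_opt_str(row["lesion_location_surgical"]),
                    severity=SeverityPanel(
                        lowest_glucose=_opt_float(row["lowest_glucose"], "patients", i, "lowest_glucose"),
                        max_glucose_infusion=_opt_float(row["max_glucose_infusion"], "patients", i, "max_glucose_infusion"),
                        insulin=_opt_float(row["insulin"], "patients", i, "insulin"),
                        proinsulin=_opt_float(row["proinsulin"], "patients", i, "proinsulin"),
                        c_peptide=_opt_float(row["c_peptide"], "patients", i, "c_peptide"),
                        insulin_to_glucose=_opt_float(row["insulin_to_glucose"], "patients", i, "insulin_to_glucose"),
                    ),
                )
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"patients row {i}: {exc}") from exc

    readings = []
    for i, row in rd.iterrows():
        try:
            readings.append(
                ScanReading(
                    patient_id=_opt_str(row["patient_id"]) or "",
                    tracer=_opt_str(row["tracer"]) or "",
                    reader_id=_opt_str(row["reader_id"]) or "",
                    timepoint_min=_req_float(row["timepoint_min"], "readings", i, "timepoint_min"),
                    suv_max_lesion=_req_float(row["suv_max_lesion"], "readings", i, "suv_max_lesion"),
                    suv_max_reference=_req_float(row["suv_max_reference"], "readings", i, "suv_max_reference"),
                    reference_region=_opt_str(row["reference_region"]) or "none",
                    visual_call=_opt_str(row["visual_call"]) or "",
                    visual_location=_opt_str(row["visual_location"]),
                )
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"readings row {i}: {exc}") from exc

    return Cohort(patients=patients, readings=readings).validate(allowed_timepoints)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return repr(value)  # shortest round-trip decimal
    return str(value)


def _write_table(path: Path, columns: Sequence[str], rows: Iterable[Sequence]) -> None:
    buf = io.StringIO()
    buf.write(",".join(columns) + "\n")
    for row in rows:
        buf.write(",".join(_fmt(v) for v in row) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def write_cohort(
    cohort: Cohort,
    patients_path: str | Path,
    genetics_path: str | Path,
    readings_path: str | Path,
    allowed_timepoints: Iterable[float] = DEFAULT_TIMEPOINTS,
) -> None:
    """Write the canonical CSV dialect (UTF-8, header row, "." decimals)."""
    cohort.validate(allowed_timepoints)
    _write_table(
        Path(patients_path),
        PATIENT_COLUMNS,
        (
            [
                p.patient_id,
                p.sex,
                p.age_at_scan_months,
                p.surgery,
                p.histology,
                p.lesion_location_surgical,
                p.severity.lowest_glucose,
                p.severity.max_glucose_infusion,
                p.severity.insulin,
                p.severity.proinsulin,
                p.severity.c_peptide,
                p.severity.insulin_to_glucose,
            ]
            for p in cohort.patients
        ),
    )
    _write_table(
        Path(genetics_path),
        GENETICS_COLUMNS,
        (
            [p.patient_id, g.gene, g.inheritance, g.pathogenicity]
            for p in cohort.patients
            for g in p.genetics
        ),
    )
    _write_table(
        Path(readings_path),
        READING_COLUMNS,
        (
            [
                r.patient_id,
                r.tracer,
                r.reader_id,
                r.timepoint_min,
                r.suv_max_lesion,
                r.suv_max_reference,
                r.reference_region,
                r.visual_call,
                r.visual_location,
            ]
            for r in cohort.readings
        ),
    )
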