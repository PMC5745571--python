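"""Gold-standard outcome assignment: histology first, genetics second.

Post-surgical histopathology is the primary reference: focal histology is a
confirmed focal case, diffuse or atypical histology a confirmed non-focal
case, and a normal histology report excludes the patient (the tissue sampled
did not establish the diagnosis).  For unoperated patients the K-ATP channel
genetics act as a secondary reference: a heterozygous paternal pathogenic
ABCC8/KCNJ11 variant predicts a focal lesion ("suspected focal"), any other
constellation — maternal, homozygous or compound-heterozygous K-ATP variants,
non-K-ATP genes, or no mutation found — predicts non-focal disease, and a
K-ATP variant of uncertain pathogenicity excludes the patient.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .cohort import Cohort, PatientRecord

__all__ = [
    "GoldLabel",
    "GoldStandardError",
    "assign_gold_label",
    "assign_all",
    "summarize_gold",
    "classifiable_labels",
    "write_gold_audit",
    "KATP_GENES",
]

KATP_GENES = frozenset({"ABCC8", "KCNJ11"})

LABELS = ("focal", "non_focal", "excluded", "suspected_focal")
SOURCES = ("histology", "genetics", "none")


class GoldStandardError(ValueError):
    """Patient attributes are inconsistent with the labelling hierarchy."""


@dataclass(frozen=True)
class GoldLabel:
    label: str
    source: str
    reason: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise GoldStandardError(f"unknown label {self.label!r}")
        if self.source not in SOURCES:
            raise GoldStandardError(f"unknown source {self.source!r}")
        if self.label == "excluded" and not self.reason:
            raise GoldStandardError("excluded label requires a reason")


def assign_gold_label(patient: PatientRecord) -> GoldLabel:
    """Assign one patient's gold-standard outcome.

    Histology (when surgery was performed) always dominates genetics.
    """
    if patient.surgery:
        if patient.histology == "none":
            raise GoldStandardError(
                f"patient {patient.patient_id}: surgery performed but no histology recorded"
            )
        if patient.histology == "focal":
            return GoldLabel("focal", "histology", "focal lesion on histopathology")
        if patient.histology in ("diffuse", "atypical"):
            return GoldLabel("non_focal", "histology", f"{patient.histology} histopathology")
        return GoldLabel("excluded", "histology", "normal histology report")

    katp = [g for g in patient.genetics if g.gene in KATP_GENES]
    if any(g.pathogenicity == "uncertain" for g in katp):
        return GoldLabel("excluded", "genetics", "variant of uncertain pathogenicity")
    if any(g.pathogenicity == "pathogenic" and g.inheritance == "paternal" for g in katp):
        return GoldLabel("suspected_focal", "genetics", "heterozygous paternal K-ATP variant")
    if katp:
        reason = "K-ATP variant inconsistent with focal disease"
    elif patient.genetics:
        reason = "non-K-ATP mutation"
    else:
        reason = "no disease-causing mutation found"
    return GoldLabel("non_focal", "genetics", reason)


def assign_all(cohort: Cohort) -> dict[str, GoldLabel]:
    return {p.patient_id: assign_gold_label(p) for p in cohort.patients}


def classifiable_labels(
    labels: dict[str, GoldLabel], count_suspected_focal: bool = False
) -> dict[str, str]:
    """Binary focal/non_focal map over the classifiable patients.

    ``suspected_focal`` patients enter as focal only when explicitly
    requested; the default drops them from test-performance denominators.
    """
    out: dict[str, str] = {}
    for pid, gl in labels.items():
        if gl.label in ("focal", "non_focal"):
            out[pid] = gl.label
        elif gl.label == "suspected_focal" and count_suspected_focal:
            out[pid] = "focal"
    return out


def summarize_gold(labels: dict[str, GoldLabel], count_suspected_focal: bool = False) -> dict:
    """Counts per (label, source) plus the classifiable total."""
    by_pair = Counter((gl.label, gl.source) for gl in labels.values())
    by_label = Counter(gl.label for gl in labels.values())
    classifiable = by_label["focal"] + by_label["non_focal"]
    if count_suspected_focal:
        classifiable += by_label["suspected_focal"]
    return {
        "n_patients": len(labels),
        "classifiable": classifiable,
        "by_label": dict(by_label),
        "by_label_source": {f"{lab}/{src}": n for (lab, src), n in sorted(by_pair.items())},
    }


def write_gold_audit(labels: dict[str, GoldLabel], path: str | Path) -> None:
    buf = io.StringIO()
    buf.write("patient_id,label,source,reason\n")
    for pid, gl in labels.items():
        reason = gl.reason.replace(",", ";")
        buf.write(f"{pid},{gl.label},{gl.source},{reason}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
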