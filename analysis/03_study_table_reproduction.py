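"""Reproduce the published test-performance table from its count inputs.

The published table prints, per method and gold-standard mode, the cohort
size with sensitivity, specificity, PPV and NPV point estimates; those
determine the 2x2 tables uniquely.  This driver recomputes every metric and
its Wilson 95% CI from the counts and prints them in the table's layout,
two decimals, half-up — the reproduction behind the exact-interval checks.

Writes: results/study_performance.csv
"""

from pathlib import Path

from focaldx.accuracy import dta_summary, round_half_up
from focaldx.study import STUDY_LOCALIZATION, STUDY_TABLES

OUT = Path(__file__).resolve().parent.parent / "results"

LAYOUT = [
    ("dopa_combined", "18F-DOPA visual / cut-off 1.44 (combined gold)"),
    ("dotanoc_visual_combined", "68Ga-DOTANOC visual (combined gold)"),
    ("dotanoc_cutoff_combined", "68Ga-DOTANOC cut-off 6.77 (combined gold)"),
    ("dopa_histology", "18F-DOPA visual / cut-off 1.44 (histology gold)"),
    ("dotanoc_visual_histology", "68Ga-DOTANOC visual (histology gold)"),
    ("dotanoc_cutoff_histology", "68Ga-DOTANOC cut-off 7.73 (histology gold)"),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = ["method,n,metric,estimate,ci_low,ci_high"]
    for key, label in LAYOUT:
        table = STUDY_TABLES[key]
        parts = []
        for m in dta_summary(table):
            if m.name == "accuracy":
                continue
            est, lo, hi = (round_half_up(v) for v in (m.estimate, m.ci_low, m.ci_high))
            rows.append(f"{key},{table.n},{m.name},{est:.2f},{lo:.2f},{hi:.2f}")
            parts.append(f"{m.name[:4]} {est:.2f} ({lo:.2f}-{hi:.2f})")
        print(f"{label}  n={table.n}")
        print("   " + ", ".join(parts))
    print("localization (surgical focal):", {
        k: f"{m}/{e}" for k, (m, e) in STUDY_LOCALIZATION.items()
    })
    (OUT / "study_performance.csv").write_text("\n".join(rows) + "\n")
    print(f"written to {OUT / 'study_performance.csv'}")


if __name__ == "__main__":
    main()
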