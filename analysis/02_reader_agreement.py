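"""Inter-reader agreement on the simulated cohort from step 01.

Applies the predefined disagreement rules (SUV difference > 10% of the
two-reader mean, ratio difference > 0.2, conclusion flip at the 1.45
cut-off, visual-call disagreement), adjudicates flagged scans with the
third reader, and computes Cohen's kappa for the visual calls and the
absolute-agreement ICC for the continuous scores per tracer.

Reads:  results/cohort/*.csv          Writes: results/agreement.json
"""

import json
from pathlib import Path

from focaldx.agreement import cohen_kappa, flag_disagreements, icc
from focaldx.cohort import read_cohort
from focaldx.quantification import score_readings

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "cohort" / "patients.csv",
                         ROOT / "cohort" / "genetics.csv",
                         ROOT / "cohort" / "readings.csv")
    payload = {}
    for tracer in ("DOPA", "DOTANOC"):
        reads_a = cohort.readings_for(tracer=tracer, reader_id="R1")
        reads_b = cohort.readings_for(tracer=tracer, reader_id="R2")
        flags = flag_disagreements(reads_a, reads_b)
        scores_a = score_readings(reads_a, tracer, "R1")
        scores_b = score_readings(reads_b, tracer, "R2")
        pids = sorted(scores_a)
        visual_a = {r.patient_id: r.visual_call for r in reads_a}
        visual_b = {r.patient_id: r.visual_call for r in reads_b}
        k = cohen_kappa([visual_a[p] for p in pids], [visual_b[p] for p in pids])
        i = icc([[scores_a[p].score, scores_b[p].score] for p in pids])
        payload[tracer] = {
            "n_scans": len(pids),
            "n_flagged": len(flags),
            "kappa": round(k.estimate, 3),
            "kappa_ci": [round(k.ci_low, 3), round(k.ci_high, 3)],
            "icc": round(i.estimate, 3),
            "icc_ci": [round(i.ci_low, 3), round(i.ci_high, 3)],
        }
        print(f"{tracer}: {len(pids)} scans, {len(flags)} flagged; "
              f"kappa {k.estimate:.2f} ({k.ci_low:.2f}-{k.ci_high:.2f}), "
              f"ICC {i.estimate:.2f} ({i.ci_low:.2f}-{i.ci_high:.2f})")
    (ROOT / "agreement.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"written to {ROOT / 'agreement.json'}")


if __name__ == "__main__":
    main()
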