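"""Multi-seed recovery: how reliably does the simulated design reproduce
the qualitative study findings?

Regenerates the calibrated cohort over 200 seeds (1,000 bootstrap
replicates each) and measures how often the DOPA ratio's AUC exceeds the
DOTANOC SUV_max's, and where the accuracy-optimal DOPA cut-off falls.
Under the printed-quantile calibration the two classes are closer in
population AUC (about 0.93 vs 0.78) than the single observed study sample
(0.98 vs 0.71), so the ordering reverses in a nontrivial fraction of
seeds — a property of the calibrated design, reported as measured.

Writes: results/recovery.json
"""

import json
from pathlib import Path

from focaldx.experiments import synthetic_recovery, wilson_coverage

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20230903


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    res = synthetic_recovery(n_seeds=200, replicates=1_000, seed=SEED)
    payload = res.asdict()
    payload["wilson_coverage"] = {
        f"p={p}": round(wilson_coverage(p, n=25, replicates=10_000, seed=SEED), 4)
        for p in (0.1, 0.5, 0.9)
    }
    (OUT / "recovery.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"{res.n_seeds} seeds, {res.replicates} bootstrap replicates each")
    print(f"  DOPA AUC superior in {100 * res.frac_dopa_auc_superior:.0f}% of seeds "
          f"(median AUCs {res.median_dopa_auc:.3f} vs {res.median_dotanoc_auc:.3f})")
    print(f"  median optimal DOPA cut-off {res.median_dopa_cutoff:.3f}")
    print(f"  Wilson coverage at n=25: {payload['wilson_coverage']}")
    print(f"written to {OUT / 'recovery.json'}")


if __name__ == "__main__":
    main()
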