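"""End-to-end analysis: gold labelling, adjudicated scoring, agreement,
test-performance tables, ROC bootstrap, tracer comparison, severity trends.

The pipeline mirrors a blinded dual-reader diagnostic-accuracy study: two
readers' serial SUV_max measurements are reconciled (predefined disagreement
rules, third-reader adjudication), a consensus score per patient and tracer
is classified visually and by cut-off against the histology/genetics gold
standard, and inference (Wilson CIs, bootstrap ROC, unpaired AUC
superiority, Mann-Whitney group contrasts, severity OLS trends) is run per
gold-standard mode.  Every stochastic stage derives its seed from the
pipeline seed and records it, so reports are bit-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import accuracy, agreement, gold_standard, quantification, roc, stats
from .cohort import Cohort, read_cohort
from .simulate import SyntheticCohort, SyntheticConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_report"]

SEVERITY_FIELDS = (
    "lowest_glucose",
    "max_glucose_infusion",
    "insulin",
    "proinsulin",
    "c_peptide",
    "insulin_to_glucose",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass(frozen=True)
class PipelineConfig:
    synthetic: Optional[SyntheticConfig] = None
    patients_path: Optional[str] = None
    genetics_path: Optional[str] = None
    readings_path: Optional[str] = None
    dopa_cutoff: float = 1.44
    dotanoc_cutoff: Optional[float] = None  # None -> re-estimated per gold mode
    gold_modes: tuple[str, ...] = ("combined", "histology_only")
    count_suspected_focal: bool = False
    replicates: int = 10_000
    seed: int = 0
    conf_level: float = 0.95

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 < self.conf_level < 1:
            raise ValueError("conf_level must lie in (0, 1)")
        bad = set(self.gold_modes) - {"combined", "histology_only"}
        if bad:
            raise ValueError(f"unknown gold modes {sorted(bad)}")


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def _load(config: PipelineConfig) -> tuple[Cohort, Optional[SyntheticCohort]]:
    if config.synthetic is not None:
        syn = generate_cohort(config.synthetic)
        return syn.cohort, syn
    if not (config.patients_path and config.genetics_path and config.readings_path):
        raise PipelineError("stage=load: need either a synthetic config or the three CSV paths")
    return read_cohort(config.patients_path, config.genetics_path, config.readings_path), None


def _series_visual_calls(readings, tracer: str) -> dict[str, str]:
    by_pid: dict[str, list] = {}
    for r in readings:
        if r.tracer == tracer:
            by_pid.setdefault(r.patient_id, []).append(r)
    return {
        pid: sorted(rows, key=lambda r: r.timepoint_min)[0].visual_call
        for pid, rows in by_pid.items()
    }


def _metrics_block(table: accuracy.ConfusionTable, conf_level: float) -> dict:
    return {
        "counts": {"tp": table.tp, "fn": table.fn, "fp": table.fp, "tn": table.tn, "n": table.n},
        "metrics": {
            m.name: {
                "estimate": m.estimate,
                "ci_low": m.ci_low,
                "ci_high": m.ci_high,
                "numerator": m.numerator,
                "denominator": m.denominator,
            }
            for m in accuracy.dta_summary(table, conf_level)
        },
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a JSON-serialisable report."""
    cohort, syn = _load(config)
    tracers = sorted({r.tracer for r in cohort.readings})
    reader_ids = sorted({r.reader_id for r in cohort.readings})
    if len(reader_ids) < 2:
        raise PipelineError("stage=readers: at least two readers are required")
    rid_a, rid_b = reader_ids[0], reader_ids[1]
    rid_c = reader_ids[2] if len(reader_ids) > 2 else None

    labels = gold_standard.assign_all(cohort)
    gold_summary = gold_standard.summarize_gold(labels, config.count_suspected_focal)
    binary = gold_standard.classifiable_labels(labels, config.count_suspected_focal)
    hist_binary = {
        pid: lab
        for pid, lab in binary.items()
        if labels[pid].source == "histology"
    }

    seeds = _child_seeds(config.seed, 4 * len(tracers) * len(config.gold_modes) + len(config.gold_modes))
    seed_iter = iter(seeds)
    seed_log: dict[str, int] = {}

    report: dict = {
        "seed": config.seed,
        "n_patients": len(cohort.patients),
        "tracers": tracers,
        "readers": reader_ids,
        "gold_summary": gold_summary,
        "agreement": {},
        "modes": {},
        "severity": {},
        "group_contrasts": {},
        "seeds": seed_log,
    }

    # --- reader agreement and adjudicated consensus, per tracer -------------
    consensus_scores: dict[str, dict[str, quantification.SuvScore]] = {}
    consensus_visual: dict[str, dict[str, str]] = {}
    flags_out = []
    for tracer in tracers:
        reads_a = cohort.readings_for(tracer=tracer, reader_id=rid_a)
        reads_b = cohort.readings_for(tracer=tracer, reader_id=rid_b)
        try:
            flags = agreement.flag_disagreements(reads_a, reads_b)
        except agreement.PairingError as exc:
            raise PipelineError(f"stage=agreement tracer={tracer}: {exc}") from exc
        if flags and rid_c is None:
            raise PipelineError(
                f"stage=adjudication tracer={tracer}: disagreements but no third reader"
            )
        reads_c = cohort.readings_for(tracer=tracer, reader_id=rid_c) if rid_c else []
        consensus, resolved = agreement.adjudicate(reads_a, reads_b, reads_c, flags)
        flags_out.extend(
            {
                "patient_id": f.patient_id,
                "tracer": f.tracer,
                "rules_triggered": list(f.rules_triggered),
                "resolved_by": f.resolved_by,
            }
            for f in resolved
        )
        calls_a = _series_visual_calls(reads_a, tracer)
        calls_b = _series_visual_calls(reads_b, tracer)
        pids = sorted(calls_a)
        kappa = agreement.cohen_kappa(
            [calls_a[p] for p in pids], [calls_b[p] for p in pids], config.conf_level
        )
        scores_a = quantification.score_readings(reads_a, tracer, rid_a)
        scores_b = quantification.score_readings(reads_b, tracer, rid_b)
        icc = agreement.icc(
            [[scores_a[p].score, scores_b[p].score] for p in pids], config.conf_level
        )
        report["agreement"][tracer] = {
            "kappa": dataclasses.asdict(kappa),
            "icc": dataclasses.asdict(icc),
            "n_flags": len(flags),
        }
        consensus_scores[tracer] = quantification.score_readings(consensus, tracer, "consensus")
        consensus_visual[tracer] = _series_visual_calls(consensus, tracer)
    report["flags"] = flags_out

    # --- test performance, ROC and tracer comparison per gold mode ----------
    for mode in config.gold_modes:
        gold = binary if mode == "combined" else hist_binary
        mode_block: dict = {"tracers": {}}
        roc_inputs: dict[str, tuple[list[float], list[str]]] = {}
        for tracer in tracers:
            scores = consensus_scores[tracer]
            eligible = [p for p in sorted(scores) if p in gold]
            if not eligible:
                continue
            svals = [scores[p].score for p in eligible]
            glabels = [gold[p] for p in eligible]
            tr_block: dict = {"n": len(eligible)}

            # visual method
            vcalls = [consensus_visual[tracer][p] for p in eligible]
            tr_block["visual"] = _metrics_block(
                accuracy.confusion_table(vcalls, glabels), config.conf_level
            )

            # cut-off method; the DOTANOC cut-off is re-estimated per mode
            if len(set(glabels)) == 2:
                s_cut = next(seed_iter)
                seed_log[f"{mode}/{tracer}/optimal_cutoff"] = s_cut
                cut_res = roc.optimal_cutoff(
                    svals, glabels, config.replicates, s_cut, config.conf_level
                )
                tr_block["optimal_cutoff"] = dataclasses.asdict(cut_res)
                if tracer == "DOPA":
                    applied_cutoff = config.dopa_cutoff
                else:
                    applied_cutoff = (
                        config.dotanoc_cutoff
                        if config.dotanoc_cutoff is not None
                        else cut_res.cutoff
                    )
                preds = [
                    quantification.classify_by_cutoff(s, applied_cutoff) for s in svals
                ]
                tr_block["cutoff"] = {
                    "applied_cutoff": applied_cutoff,
                    **_metrics_block(
                        accuracy.confusion_table(preds, glabels), config.conf_level
                    ),
                }
                s_auc = next(seed_iter)
                seed_log[f"{mode}/{tracer}/bootstrap_auc"] = s_auc
                roc_res = roc.bootstrap_auc(
                    svals, glabels, config.replicates, s_auc, config.conf_level
                )
                tr_block["roc"] = {
                    "auc": roc_res.auc,
                    "auc_ci": list(roc_res.auc_ci),
                    "n_pos": roc_res.n_pos,
                    "n_neg": roc_res.n_neg,
                    "thresholds": list(roc_res.thresholds),
                    "sens_points": list(roc_res.sens_points),
                    "spec_points": list(roc_res.spec_points),
                }
                roc_inputs[tracer] = (svals, glabels)

            frac, matches, n_elig, _per = quantification.localization_concordance(
                scores, cohort.patients
            )
            tr_block["localization"] = {
                "fraction": frac,
                "matches": matches,
                "eligible": n_elig,
            }
            mode_block["tracers"][tracer] = tr_block

        if "DOPA" in roc_inputs and "DOTANOC" in roc_inputs:
            s_cmp = next(seed_iter)
            seed_log[f"{mode}/compare_auc"] = s_cmp
            cmp_res = roc.compare_auc_unpaired(
                *roc_inputs["DOPA"], *roc_inputs["DOTANOC"],
                replicates=config.replicates, seed=s_cmp,
            )
            mode_block["auc_comparison_dopa_vs_dotanoc"] = dataclasses.asdict(cmp_res)
        report["modes"][mode] = mode_block

    # --- group contrasts and severity trends (combined gold standard) ------
    for tracer in tracers:
        scores = consensus_scores[tracer]
        focal_scores = [scores[p].score for p in sorted(scores) if binary.get(p) == "focal"]
        nonfocal_scores = [
            scores[p].score for p in sorted(scores) if binary.get(p) == "non_focal"
        ]
        if focal_scores and nonfocal_scores:
            report["group_contrasts"][tracer] = dataclasses.asdict(
                stats.mann_whitney_u(focal_scores, nonfocal_scores)
            )

    if "DOPA" in consensus_scores:
        scores = consensus_scores["DOPA"]
        focal_pids = [p for p in sorted(scores) if binary.get(p) == "focal"]
        ratio = [scores[p].score for p in focal_pids]
        for name in SEVERITY_FIELDS:
            values = [getattr(cohort.patient(p).severity, name) for p in focal_pids]
            complete = sum(v is not None for v in values)
            if complete < 3 or len(set(ratio)) < 2:
                report["severity"][name] = {"skipped": f"{complete} complete pairs"}
                continue
            trend = stats.linear_trend(ratio, values)
            report["severity"][name] = dataclasses.asdict(trend)

    return report


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write the structured outputs: performance.csv, roc.json,
    agreement.json, comparisons.json and a human-readable report.md."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = ["mode,tracer,method,n,metric,estimate,ci_low,ci_high,localization_fraction"]
    for mode, mb in report["modes"].items():
        for tracer, tb in mb["tracers"].items():
            loc = tb["localization"]["fraction"]
            loc_s = "" if loc is None else f"{loc:.6g}"
            for method in ("visual", "cutoff"):
                if method not in tb:
                    continue
                for name, m in tb[method]["metrics"].items():
                    rows.append(
                        f"{mode},{tracer},{method},{tb[method]['counts']['n']},{name},"
                        f"{m['estimate']:.6g},{m['ci_low']:.6g},{m['ci_high']:.6g},{loc_s}"
                    )
    (out / "performance.csv").write_text("\n".join(rows) + "\n", encoding="utf-8")

    roc_payload = {
        mode: {
            "tracers": {
                tracer: {k: tb[k] for k in ("roc", "optimal_cutoff") if k in tb}
                for tracer, tb in mb["tracers"].items()
            },
            "auc_comparison_dopa_vs_dotanoc": mb.get("auc_comparison_dopa_vs_dotanoc"),
        }
        for mode, mb in report["modes"].items()
    }
    (out / "roc.json").write_text(
        json.dumps(_round_floats(roc_payload), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    (out / "agreement.json").write_text(
        json.dumps(
            _round_floats({"agreement": report["agreement"], "flags": report["flags"]}),
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )
    (out / "comparisons.json").write_text(
        json.dumps(
            _round_floats(
                {"group_contrasts": report["group_contrasts"], "severity": report["severity"]}
            ),
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )

    lines = [
        "# Diagnostic-accuracy report",
        "",
        f"Patients: {report['n_patients']}; classifiable: {report['gold_summary']['classifiable']}",
        f"Tracers: {', '.join(report['tracers'])}; readers: {', '.join(report['readers'])}",
        f"Pipeline seed: {report['seed']}",
        "",
    ]
    for mode, mb in report["modes"].items():
        lines.append(f"## Gold standard: {mode}")
        for tracer, tb in mb["tracers"].items():
            lines.append(f"### {tracer} (n = {tb['n']})")
            for method in ("visual", "cutoff"):
                if method not in tb:
                    continue
                ms = tb[method]["metrics"]
                summary = ", ".join(
                    f"{k} {v['estimate']:.2f} ({v['ci_low']:.2f}-{v['ci_high']:.2f})"
                    for k, v in ms.items()
                )
                lines.append(f"- {method}: {summary}")
            if "roc" in tb:
                r = tb["roc"]
                lines.append(
                    f"- AUC {r['auc']:.2f} ({r['auc_ci'][0]:.2f}-{r['auc_ci'][1]:.2f})"
                )
            if "optimal_cutoff" in tb:
                c = tb["optimal_cutoff"]
                lines.append(
                    f"- optimal cut-off {c['cutoff']:.2f} "
                    f"({c['cutoff_ci'][0]:.2f}-{c['cutoff_ci'][1]:.2f})"
                )
        cmp_res = mb.get("auc_comparison_dopa_vs_dotanoc")
        if cmp_res:
            lines.append(
                f"- DOPA vs DOTANOC AUC difference {cmp_res['difference']:.2f}, "
                f"p = {cmp_res['p_value']:.3g}"
            )
        lines.append("")
    (out / "report.md").write_text("\n".join(lines), encoding="utf-8")
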