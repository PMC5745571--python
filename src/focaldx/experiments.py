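"""Simulation experiments over the synthetic cohort and interval estimators.

These are the property-level checks the analysis rests on: Wilson-interval
coverage under repeated binomial sampling, and recovery of the qualitative
study findings (DOPA outperforms DOTANOC; the optimal DOPA ratio cut-off
sits between the two class distributions) across many synthetic cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import agreement, quantification, roc
from .accuracy import wilson_ci
from .gold_standard import assign_all, classifiable_labels
from .simulate import SyntheticConfig, generate_cohort

__all__ = ["wilson_coverage", "synthetic_recovery", "RecoveryResult"]


def wilson_coverage(
    p: float,
    n: int = 25,
    replicates: int = 10_000,
    conf_level: float = 0.95,
    seed: int = 0,
) -> float:
    """Empirical coverage of the Wilson interval over binomial draws.

    Draws ``replicates`` binomial(n, p) counts and returns the fraction
    whose Wilson interval contains p.  Intervals depend on the count alone,
    so they are evaluated once per distinct count.
    """
    rng = np.random.default_rng(seed)
    counts = rng.binomial(n, p, size=replicates)
    covered_by_k = np.array(
        [lo <= p <= hi for k in range(n + 1) for lo, hi in [wilson_ci(k, n, conf_level)]]
    )
    return float(covered_by_k[counts].mean())


@dataclass(frozen=True)
class RecoveryResult:
    n_seeds: int
    replicates: int
    frac_dopa_auc_superior: float
    median_dopa_cutoff: float
    median_dopa_auc: float
    median_dotanoc_auc: float
    median_dopa_auc_ci: tuple[float, float]

    def asdict(self) -> dict:
        d = dataclasses.asdict(self)
        d["median_dopa_auc_ci"] = list(self.median_dopa_auc_ci)
        return d


def _tracer_scores(syn, tracer: str) -> tuple[list[float], list[str]]:
    """Classifiable adjudicated-consensus scores and gold labels, per tracer."""
    labels = classifiable_labels(assign_all(syn.cohort))
    rid_a, rid_b, rid_c = syn.reader_ids
    reads_a = syn.cohort.readings_for(tracer=tracer, reader_id=rid_a)
    reads_b = syn.cohort.readings_for(tracer=tracer, reader_id=rid_b)
    reads_c = syn.cohort.readings_for(tracer=tracer, reader_id=rid_c)
    flags = agreement.flag_disagreements(reads_a, reads_b)
    consensus, _ = agreement.adjudicate(reads_a, reads_b, reads_c, flags)
    scores = quantification.score_readings(consensus, tracer, "consensus")
    pids = [p for p in sorted(scores) if p in labels]
    return [scores[p].score for p in pids], [labels[p] for p in pids]


def synthetic_recovery(
    n_seeds: int = 200,
    replicates: int = 1_000,
    seed: int = 0,
    config: SyntheticConfig | None = None,
) -> RecoveryResult:
    """Regenerate the cohort over many seeds and measure how often the DOPA
    ratio outperforms the DOTANOC SUV_max (bootstrap AUCs), plus the median
    accuracy-optimal DOPA cut-off."""
    base = config or SyntheticConfig()
    master = np.random.SeedSequence(seed)
    gen_seeds = [int(s.generate_state(1)[0] % 2**31) for s in master.spawn(3 * n_seeds)]
    superior = 0
    cutoffs, aucs_dopa, aucs_dota, ci_lo, ci_hi = [], [], [], [], []
    for i in range(n_seeds):
        syn = generate_cohort(dataclasses.replace(base, seed=gen_seeds[3 * i]))
        s_d, l_d = _tracer_scores(syn, "DOPA")
        s_t, l_t = _tracer_scores(syn, "DOTANOC")
        res_d = roc.bootstrap_auc(s_d, l_d, replicates, gen_seeds[3 * i + 1])
        res_t = roc.bootstrap_auc(s_t, l_t, replicates, gen_seeds[3 * i + 2])
        cut = roc.optimal_cutoff(s_d, l_d, replicates, gen_seeds[3 * i + 1])
        if res_d.auc > res_t.auc:
            superior += 1
        cutoffs.append(cut.cutoff)
        aucs_dopa.append(res_d.auc)
        aucs_dota.append(res_t.auc)
        ci_lo.append(res_d.auc_ci[0])
        ci_hi.append(res_d.auc_ci[1])
    return RecoveryResult(
        n_seeds=n_seeds,
        replicates=replicates,
        frac_dopa_auc_superior=superior / n_seeds,
        median_dopa_cutoff=float(np.median(cutoffs)),
        median_dopa_auc=float(np.median(aucs_dopa)),
        median_dotanoc_auc=float(np.median(aucs_dota)),
        median_dopa_auc_ci=(float(np.median(ci_lo)), float(np.median(ci_hi))),
    )
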