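# Methods

## Scores and classification

Each scan series is a set of acquisition timepoints (default allowed set
{10, 30, 45, 60} min, configurable) with a lesion-region and a
reference-region SUV_max in g/ml. The 18F-DOPA score is the per-timepoint
lesion/reference ratio maximized over the series; the 68Ga-DOTANOC score is
the absolute lesion SUV_max maximized over the series. Timepoint ties break
toward the earliest acquisition, so the reported "time of maximum" is
deterministic. Cut-off classification uses a **strict** inequality
(score > cutoff ⇒ focal): the convention is unstated in the source
material, and with reported cut-offs lying strictly between the observed
class scores (1.44 sits between the non-focal 1.20 bulk and the focal
minimum 1.47) the two conventions are observationally equivalent there; the
choice is documented and tested.

## Gold standard

Histology after surgery dominates: focal ⇒ focal; diffuse/atypical ⇒
non-focal; normal report ⇒ excluded. Without surgery, K-ATP genetics
decide: any ABCC8/KCNJ11 variant of uncertain pathogenicity ⇒ excluded
(checked before the paternal rule, so uncertainty always wins);
heterozygous paternal pathogenic ⇒ *suspected focal*, a distinct label
excluded from test-performance denominators by default (the studied cohort
contained none, so the category is untested empirically and is not silently
merged into "focal"); everything else — maternal, homozygous,
compound-heterozygous, non-K-ATP genes, no mutation — ⇒ non-focal.
Analyses run in two modes: *combined* (histology or genetics) and
*histology_only* (the surgical subset).

## Dual-reader protocol

Two blinded readers measure every scan; a third adjudicates. A series is
flagged when any rule fires: (1) a matched SUV_max pair differs by more
than 10% — the denominator, unstated in the source, is the **two-reader
mean**, chosen for symmetry and applied at every matched timepoint; (2) the
two time-maximum ratios differ by more than 0.2; (3) the ratio
classifications at the predefined cut-off 1.45 disagree (DOPA only);
(4) the visual calls disagree. Flagged series take the adjudicator's values
wholesale (recorded in `resolved_by`); unflagged series average the two
readers' SUVs. Note the 10% rule is strict: with two independent 5%-CV
readers and six matched measurements per DOPA series, most series are
flagged — an intended property of a conservative protocol, not an error.

Agreement statistics: Cohen's kappa with the Fleiss–Cohen–Everitt
large-sample variance and a normal-approximation CI clamped to [-1, 1]
(constant, equal raters yield an explicit "undefined" result); ICC as the
two-way random-effects, single-rater, **absolute-agreement** form
(ICC(2,1)) with F-distribution CI bounds, the form that penalizes a
systematic between-reader shift. The consistency form ICC(3,1) is exposed
alongside because the source material does not name its model; no
reproduction of the published 0.96 is claimed (reader-level data are
unpublished).

## Test metrics and intervals

Sensitivity, specificity, PPV, NPV and accuracy are binomial proportions
on their own numerator/denominator; a zero denominator yields an *absent*
metric, never 0. All CIs are plain Wilson score intervals (no continuity
correction); this choice reproduces all published interval bounds at two
decimals, verified in the test suite against the 2×2 tables implied by the
published counts and point estimates. Display rounding is half-up to two
decimals; full precision is kept internally.

## ROC, bootstrap, cut-off, superiority

Candidate thresholds are midpoints of consecutive sorted unique scores,
bracketed by ±∞ sentinels — the published 1.44 lies between observed class
values, implying an interpolated threshold, and midpoints are the simplest
deterministic interpolation. The empirical AUC equals the concordant-pair
fraction with ties at half weight (tested against exhaustive enumeration,
and against the Mann–Whitney identity U/(n₁n₂) = AUC).

Bootstrap inference resamples **stratified** (positives and negatives
independently, class sizes preserved) so no replicate degenerates to one
class at these small n; an unstratified switch exists. CIs are percentile
(2.5/97.5); 10,000 replicates by default; all draws come from a seeded
generator and results are bit-reproducible. The accuracy-maximizing
cut-off ties break toward the lowest candidate; its CI is the percentile
interval of per-replicate optima (each replicate searching its own midpoint
grid). Tracer superiority uses a non-paired bootstrap: both cohorts
resampled independently, D = (AUC₁ − AUC₂)/sd_boot referred to the standard
normal; two-sided by default with a one-sided option, since the source
reports a "superiority" p without stating sidedness. Zero bootstrap
variance with a nonzero difference reports p = 1/replicates with a
degenerate-variance flag.

Group contrasts use Mann–Whitney U (exact enumeration when n₁n₂ ≤ 400 and
no ties, else the tie-corrected normal approximation with continuity
correction — a deterministic hybrid). Severity associations are
univariable OLS fits of each biomarker on the focal DOPA ratio with a
two-sided slope t-test (n − 2 df); missing pairs are dropped and counted.

## Synthetic cohort

The generator emulates the study structure exactly at defaults: 55
patients — 22 histology-focal, 29 non-focal (11 histology, 18 genetics,
using the published genetics spectrum), 4 excluded (1 normal histology,
3 uncertain K-ATP variants) — with 53 DOPA and 18 DOTANOC scans (9 focal +
7 non-focal classifiable DOTANOC, two of them DOTANOC-only patients).

Class scores are log-normal, location = ln(median) and scale =
(ln q₃ − ln q₁)/(2 z₀.₇₅) from the published per-class quantiles: DOPA
ratio 1.72 (1.58–2.27) focal, 1.12 (1.05–1.20) non-focal; DOTANOC SUV_max
9.43 (5.86–12.51) focal, 4.71 (3.27–6.98) non-focal. The focal DOPA
quantiles are strongly log-asymmetric, so no log-normal matches all three
printed values; anchoring the median (the formula above is then also the
least-squares quartile fit) is the chosen compromise, and the calibration
object reports the residual. Per-timepoint SUVs are constructed so the
time-maximum equals the latent score, with the maximizing timepoint drawn
from the observed frequencies (DOPA 10/30/60 min at 12/13/24 of 49;
DOTANOC acquisition patterns at their observed frequencies) and
non-maximal timepoints damped by U(0.75, 0.97). Reference-region SUVs are
log-normal around 4 g/ml (log-SD 0.15, plausible normal-pancreas uptake).

Reader error is multiplicative log-normal noise per measurement
(default CV 5%, a plausible blinded re-measurement spread; it yields ICCs
near the published 0.96) and visual calls flip the latent class with
probability 0.05 (kappa near the published 0.74). Severity biomarkers
(glucose, glucose demand, insulin panel) are drawn **independently of the
scores** by default, encoding the study's null association; an association
knob exists for power studies. The printed glucose-demand median "18.5"
lies outside its own printed IQR (4.4–12.1); the generator reads this as a
typeset leading digit and uses 8.5. Proinsulin and C-peptide quantiles are
unpublished and set to clinically plausible values. One published feature
is deliberately absent: giant focal lesions (none occurred in the series).

What passing tests show — and do not show: the generator matches the
study's *marginal score distributions and cohort structure*, not
patient-level data; correlations between tracers within a patient,
reader-error covariance, and the heavy right tail of the focal ratio
distribution (range up to 4.69) are not reproduced, so results on real
data may differ.

## Problem sizes and known limitations

The recovery experiment uses 200 regenerated cohorts with 1,000 bootstrap
replicates each, and interval coverage uses 10,000 binomial draws per
setting — sizes at which the Monte-Carlo error is well below the effects
measured. Under the printed-quantile calibration the population AUCs are
≈0.93 (DOPA ratio) and ≈0.78 (DOTANOC SUV_max) — closer together than the
single observed sample (0.98 vs 0.71) — and with only 9+7 classifiable
DOTANOC patients the sample-AUC spread is wide, so the DOPA > DOTANOC
ordering holds in roughly 80–90% of seeds rather than always; the
recovery driver reports this as measured. Exact reproduction of the
published AUC 0.98 (0.93–1), cut-off 1.44 (1.35–1.46), kappa 0.74 and ICC
0.96 is impossible without patient-level scores and is not attempted;
the package instead verifies the *methods* against independent oracles
and the published interval arithmetic exactly.
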