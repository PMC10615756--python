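# Methods

## Data model and normalization

A cohort is an expression matrix (probesets × visit samples, assumed
array-normalized, e.g. RMA on a log₂ scale) joined to one visit record per
sample: subject id, 1-based visit index, gender (M/F), primary diagnosis
(BP, MDD, SZ, SZA, PTSD), SAS-4 state-anxiety score (0–100), optional STAI
State score (20–80), and optional follow-up outcomes (first-year and
any-future hospitalization flags, time-to-first-hospitalization and censor
time in decimal years from the visit). Missing phenotype fields stay
missing; nothing is imputed.

Before cohorts are combined, each probeset is z-scored within gender ×
primary-diagnosis strata, using the sample standard deviation (ddof = 1).
Whether strata should instead pool schizophrenia with schizoaffective is
genuinely open; we default to primary diagnosis and expose the grouping as
a callable, reserving the pooled PSYCHOSIS group for stratified prediction
reporting only. Zero-variance probesets within a stratum map to z = 0 with
a warning; a singleton stratum is a hard error. The normalizer can be
frozen on one cohort and applied to another, which keeps the validation
comparison out-of-sample. Transforming a cohort containing a stratum never
seen at fit time falls back to the fit cohort's pooled parameters.

State labels are threshold-inclusive: LOW at SAS-4 ≤ 40, HIGH at ≥ 60,
SEVERE when a HIGH visit also has STAI ≥ 55 (a HIGH visit with missing
STAI is never SEVERE), INTERMEDIATE otherwise. Intermediate visits take no
part in discovery pairing.

## Step 1 — discovery

Diametric pairs are consecutive visits of one subject whose labels flip
between LOW and high-anxiety (HIGH or SEVERE); an all-pairs variant is
available but not the default, since state sampling is per visit.
Differential-expression concordance uses a 1.2-fold threshold (0.263 on the
log₂ scale) on the raw (pre-z-scoring) within-subject change — the exact
differential statistic used by any given upstream array pipeline may
differ, so the threshold is configuration. Absent/Present concordance
counts detection-call flips. The probeset's direction is the sign of the
summed concordances (ties resolve to "increased" deterministically); the
percent-of-maximum denominator is *all* diametric pairs, so a pair in which
the probeset is silent counts against it (an informative-pairs-only
denominator is available by flag). Points: ≥ 33% → 2, ≥ 50% → 4, ≥ 80% → 6,
boundaries inclusive. A probeset scored by both methods keeps the maximum;
DE wins exact ties.

## Step 2 — prioritization

Evidence rows are (gene, species ∈ {human, animal}, kind ∈ {genetic,
brain expression, peripheral expression, protein}, weight ∈ (0, 2]).
Protein evidence folds into the expression category of its tissue
(peripheral when unspecified). Six categories, each capped at 2 points,
reconstruct the 12-point maximum; the per-category weighting beyond the cap
is not externally fixed, so the scheme is a configurable default. Probesets
without a gene annotation score 0 evidence points but remain eligible
through discovery points. The combined gate is ≥ 6 of 18, inclusive.

## Step 3 — validation

Group means are computed on z-scored expression with visits as the unit of
observation (the repeated-visits-as-subjects alternative is a known
modeling choice we did not take; group legends in this design count
testing visits). Stepwise change requires strict inequalities —
low < high < severe for increased markers, reversed for decreased — since
ties on continuous z-scores are measure-zero and "stepwise changed" implies
an ordering. Significance is one-way fixed-effects ANOVA
(`scipy.stats.f_oneway`); a degenerate fit with zero between-group variance
reports p = 1. Points: not stepwise → 0; stepwise with p ≥ 0.05 → 2;
0.05 > p ≥ 0.05/n_candidates → 4; smaller → 6. The 6-point Bonferroni tier
is an extrapolation of the tier structure (no published row exhibits it)
and can be capped at 4 by flag. CFE3 = discovery + evidence + validation
(≤ 24); the top-candidate gate is CFE3 ≥ 8, one third of the maximum.

## Step 4 — predictive testing

Positive classes: high anxiety state = visits with SAS-4 ≥ 60 versus all
other test visits; severe state = SEVERE visits versus the rest;
first-year hospitalization = visits followed by an anxiety-contributory
hospitalization within one year. Published stratum cells print
(positives/total) pairs, which fixes the positives-versus-rest convention.
Repeated visits are treated as independent observations cross-sectionally;
a subject-level aggregation flag exists.

AUC equals the Mann-Whitney U statistic divided by n₊·n₋ (ties counted ½),
computed after orienting values so the discovery direction predicts the
positive class; the p-value is the one-sided asymptotic Mann-Whitney test
with tie correction. The implementation is checked exactly against a
brute-force all-pairs oracle in the test suite.

The longitudinal mode summarizes each subject with ≥ 2 visits by four
features — last level, maximum level, slope into the most recent visit,
maximum inter-visit slope — each z-scored across the subjects of the
evaluation stratum and averaged into one combined predictor. How the four
features should be integrated is underdetermined; the equal-weight z-mean
is the simplest symmetric choice.

All-future hospitalization risk uses a univariate Cox proportional-hazards
fit (lifelines) of time from visit to first future hospitalization on the
stratum-z-scored marker, reporting exp(β) per 1-sd increase and the Wald
p-value. Zero events or a constant marker are errors; non-convergent fits
are flagged and excluded from scoring. Strata need ≥ 2 observations per
class (AUC) or ≥ 3 events (hazards) to be reported; smaller ones are
skipped with a log line.

Per-category points use the maximum rule — 3 for any significant
all-subject result, else 2 for a gender stratum, else 1 for a gender ×
diagnosis stratum — with either mode (cross-sectional or longitudinal)
counting. An additive rule was rejected because it fails every published
composite-score arithmetic check that the maximum rule passes; that
reconstruction is asserted for all 19 reference-panel rows in the test
suite. The Bonferroni flag for headline claims divides 0.05 by the number
of candidates tested (95 for the reference panel) with strict inequality.

## Composite score, panels, report

CFE4 = CFE3 + the four per-category points (≤ 36: 24 from the study's own
cohorts, 12 from literature). Panels filter at CFE3 ≥ 8 and rank by CFE4
(ties: CFE3, then probeset id). The BioM-N aggregate is the mean of
direction-aligned z-scores over measured members; missing members are
dropped and counted.

The clinician report digitizes each concordant panel marker against
reference group means (high vs low anxiety; hospitalized vs not, first-year
and all-future): for an increased marker 1 at or above the high-group mean,
0 at or below the low-group mean, 0.5 in between, mirrored for decreased
markers. Non-concordant markers (high-group mean on the wrong side) are
excluded from that report's denominator and listed in the output. The risk
percentile is 100 · Σscores / n_included; the chronic-risk score is the
arithmetic mean of the two hospitalization percentiles (the combination
method is otherwise unspecified; the mean is the neutral choice). Drug
matching restricts the drug-gene table to opposite-direction modulators;
each drug's percentile is 100 · Σ(matched marker scores) / (number of the
patient's markers scoring ≥ 0.5), undefined when the denominator is zero.
Panel-level drug coverage divides by unique gene symbols (18 for the
19-probeset reference panel, which carries NTRK3 twice); a probeset-level
denominator is available by flag.

## Synthetic cohorts

The generator emulates the study conditions: a discovery arm (default 60
subjects) whose subjects alternate LOW/HIGH SAS-4 targets across 2–5
visits (visit-count distribution 32:21:3:2 over 2/3/4/5 visits, matching
the published discovery cohort; gender mix 41:17 M:F), guaranteeing at
least one diametric pair per subject; a validation arm (40 subjects, one
severe visit each, SAS-4 ≥ 60 with STAI ≥ 55); and a test arm (200
subjects) with uniform SAS-4, 3–6-month visit spacing, and follow-up
outcomes.

Expression = per-probeset baseline (uniform 4–10, log₂-like) + subject
random effect (sd 0.5) + direction-aligned planted shifts + N(0, noise_sd)
measurement noise, with noise_sd = 1 so effects are in measurement-sd
units. Planted state markers (default 20 of 2000 probesets) shift by
state_effect = 1.0 at high-anxiety visits plus severe_extra_effect = 0.5 in
severe anxiety (which is what makes the stepwise validation pattern
recoverable); planted trait markers (default 20) shift with a subject-level
liability. Detection calls threshold expression at 6.0, the middle of the
baseline range. Hospitalization times are exponential with per-subject
log-hazard = trait_log_hazard (default ln 2) × the subject's mean z-scored
direction-aligned trait-marker expression, around a base hazard of
0.12/year, censored uniformly at 2–12 years. A single seed fans out to
per-component substreams (SeedSequence.spawn), so identical configurations
are bit-identical.

The simulated evidence table annotates each planted gene's six categories
independently with probability `sensitivity` (default 0.8) and null genes
with `false_positive_rate` (default 0.05), at the per-category cap weight.

What the generator does *not* emulate: probe-level microarray physics,
batch and medication effects, diagnosis-specific expression differences,
correlated probesets of one gene, informative visit timing, or competing
risks. Passing recovery tests therefore demonstrates that the scoring
machinery ranks planted signal above independent Gaussian noise under the
stated effect sizes — not that the framework would achieve comparable
enrichment on real microarray data, where null probesets are correlated
and evidence annotations are far from independent.

## Numerical choices

- Sample sd (ddof = 1) everywhere a standard deviation is taken.
- ANOVA p clamped away from 0 at the smallest positive double before the
  validation tier mapping (the mapping needs p ∈ (0, 1]).
- Deterministic tie-breaks: direction ties → "increased"; best-method ties
  → DE; candidate and panel orderings break ties by probeset id.
- Cohort CSVs are written with `%.17g` and read with round-trip float
  precision, so write → read is the identity on doubles.
- Thresholds (40/60/55, 33/50/80, gates 6 and 8, α = 0.05) are
  boundary-inclusive exactly as printed, except the Bonferroni flag, which
  is strict.

## Problem sizes used by the test suite

Unit and property tests run on small simulated cohorts (≈ 100–500
probesets, 15–60 subjects). The planted-marker recovery check runs the
full default conditions (2000 probesets, 20 state markers at 1.0 sd,
60/40/200 subjects) over 20 seeds and requires ≥ 70% of planted state
markers in the top decile of the CFE3 ranking in every seed; hazard-ratio
recovery uses n = 500 subjects at a true ratio of 2. The whole suite
completes in well under a minute on one CPU.

## Known limitations

- The original cohort's expression data is not public, so the published
  headline predictions (individual AUCs, hazard ratios, the 95-probeset
  survivor count) cannot be recomputed; only the scoring arithmetic of the
  published panel, the stated statistical properties of each operation,
  and synthetic recovery are verifiable.
- The published drug-coverage table is only partially consistent with the
  published per-biomarker drug annotations (e.g. clozapine, omega-3, gamma
  frequency); only the valproate cell reconstructs exactly, and it is the
  only anchored value.
- "Cox regression odds ratio" in the published tables is implemented and
  reported as a hazard ratio.
- Plain fixed-effects ANOVA ignores repeated visits per subject; a
  mixed-model variant is out of scope by design.
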