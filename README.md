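# anxiomark

Blood gene-expression biomarkers for anxiety: a four-step discovery,
prioritization, validation, and predictive-testing pipeline, with composite
evidence scoring, biomarker panels, and a digitized clinician report.

## Who this is for

Psychiatric-genomics researchers who want a tested, reusable implementation
of the within-subject longitudinal biomarker framework used to nominate
blood transcriptomic markers of anxiety state and of future anxiety-related
hospitalizations. Because the original patient-level cohort data was never
deposited, the package ships a synthetic-cohort generator with planted
markers, so every stage can be exercised, calibrated, and regression-tested
end to end.

## The method

Subjects with major psychiatric disorders (bipolar, depression,
schizophrenia, schizoaffective, PTSD) are phenotyped at repeated visits with
a 0–100 visual analog anxiety scale (SAS-4; low state ≤ 40, high state
≥ 60) and the STAI State inventory (≥ 55 marks clinically severe anxiety).

1. **Discovery (up to 6 pts).** Within each subject, consecutive visits
   whose anxiety labels flip between LOW and HIGH form *diametric pairs*.
   A probeset earns a concordance score across all pairs via differential
   expression (log₂ change beyond a 1.2-fold threshold) and Absent/Present
   detection-call flips; its percent-of-maximum maps to internal points:
   ≥ 33% → 2, ≥ 50% → 4, ≥ 80% → 6.
2. **Prioritization (up to 12 pts).** Gene-level convergent literature
   evidence — genetic, brain expression, peripheral expression, in human
   and animal — is summed in six capped categories (2 pts each).
   Candidates with combined discovery + evidence ≥ 6 (of 18) advance.
3. **Validation (up to 6 pts).** Candidates must change stepwise across
   z-scored group means: discovery-low → discovery-high → independent
   severe-anxiety cohort, strictly monotone in the discovery direction.
   One-way ANOVA across the three groups grades significance: stepwise
   only → 2, nominal p < 0.05 → 4, Bonferroni-surviving → 6. The running
   total CFE3 (≤ 24) gates top candidates at ≥ 8.
4. **Testing (up to 3 pts × 4 targets).** In a held-out cohort, each top
   candidate predicts four targets — high anxiety state, clinically severe
   state, first-year hospitalization (ROC AUC / Mann-Whitney), and all
   future hospitalizations (Cox proportional hazards per 1-sd) — in all
   subjects, per gender, and per gender × diagnosis, cross-sectionally and
   longitudinally. Per target: 3 pts if significant in all subjects, else
   2 in a gender, else 1 in a gender × diagnosis stratum (maximum rule).

The composite **Convergent Functional Evidence** score CFE4 = CFE3 + the
four per-target points, capped at 36 (24 from the study's own cohorts, 12
from literature). Top panels (BioM-N) aggregate members as a
direction-aligned mean z-score. The clinician report digitizes a patient's
panel expression against high/low reference group means (1 / 0.5 / 0),
yields percentile risk scores for state and chronic hospitalization risk,
and ranks drugs known to modulate the patient's elevated markers in the
opposite direction.

Expression is assumed array-normalized upstream; all cohorts are z-scored
per probeset within gender × diagnosis strata before being combined.

## Worked example

```python
from anxiomark.pipeline import PipelineConfig, run_pipeline
from anxiomark.simulate import SimulationConfig

cfg = PipelineConfig(simulation=SimulationConfig(
    n_subjects_discovery=30, n_subjects_validation=20, n_subjects_test=60,
    n_probesets=500, n_state_markers=10, n_trait_markers=10),
    seed=7, panel_size=10)
run_pipeline(cfg, "demo")
```

The run directory contains the per-stage tables; the head of
`demo/scorecards.csv`:

```
probeset   gene_symbol  direction  discovery_points  cfg_points  validation_points  cfe3  cfe4
ps00056_at      G00056  decreased                 4        10.0                  6  20.0  29.0
ps00098_at      G00098  decreased                 4        12.0                  6  22.0  28.0
ps00357_at      G00357  increased                 4        12.0                  6  22.0  28.0
ps00395_at      G00395  decreased                 4        12.0                  6  22.0  28.0
ps00444_at      G00444  decreased                 4        10.0                  6  20.0  27.0
```

With these settings all 10 of the top 10 probesets by CFE4 are planted
markers (see `demo/truth.csv`). A clinician report for one test subject
(`demo/report_T0000.txt`):

```
Anxiety biomarker panel report — subject T0000

Current anxiety state                15.0 %
First-year hospitalization risk      28.6 %
Future hospitalization risk          40.0 %
Combined chronic risk                34.3 %
```

meaning: at the most recent visit 15% of the panel's digitized weight sits
above this subject's demographic high-anxiety reference levels, while about
a third of the hospitalization-referenced markers are elevated — a
low-state, moderate-chronic-risk profile.

The same flow is available from the shell:

```
anxiomark all --out demo --seed 7
anxiomark report --out demo --subject T0003
```

The package also ships the published 19-probeset / 18-gene reference panel
(`anxiomark.reference`) with its per-step score components, directions, and
opposite-direction drug annotations, used for composite-score arithmetic
and drug-coverage calculations, e.g.:

```python
from anxiomark.reference import panel_genes, panel_directions, \
    reference_drug_table, TOP19_PANEL
from anxiomark.report import drug_coverage

cov = drug_coverage(panel_genes(),
                    {r["gene"]: r["direction"] for r in TOP19_PANEL},
                    reference_drug_table())
print(round(cov["Valproate"], 2))   # 33.33 — valproate covers 6 of 18 genes
```

## Layout

- `anxiomark.cohort` — data model, IO, state labeling, stratified z-scoring
- `anxiomark.simulate` — synthetic cohorts with planted state/trait markers
- `anxiomark.discovery`, `.cfg`, `.validation`, `.prediction` — steps 1–4
- `anxiomark.cfe` — composite scoring and panels
- `anxiomark.report` — digitization, risk percentiles, drug matching
- `anxiomark.reference` — the published 19-probeset reference panel
- `anxiomark.pipeline` / `anxiomark.cli` — orchestration and CLI

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
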