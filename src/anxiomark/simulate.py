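"""Synthetic longitudinal cohort generator with planted biomarkers.

Emulates the statistical structure the four-step pipeline assumes: a
discovery cohort of psychiatric subjects with 2-5 visits each and at least
one diametric change in anxiety state between consecutive visits (SAS-4
<=40 to >=60 or vice versa), a validation arm with clinically severe
anxiety (SAS-4 >=60 and STAI State >=55), and an independent test cohort
with follow-up hospitalization outcomes.

Expression is generated on a log2-like microarray scale: per-probeset
baseline, a per-subject random effect, a direction-aligned shift of
``state_effect`` (in units of ``noise_sd``) at high-anxiety visits for the
planted state markers (plus ``severe_extra_effect`` in severe anxiety), a
subject-level liability shift for the planted trait markers, and Gaussian
measurement noise. Present/Absent detection calls are thresholded
expression. Hospitalizations follow an exponential time-to-event model
whose log-hazard is ``trait_log_hazard`` times the subject's mean z-scored
trait-marker expression.

The generator does not emulate probe-level microarray physics, batch
effects, or medication effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ExpressionMatrix, VisitRecord, label_state, StateLabel

#: Visits-per-subject distribution matching the published discovery cohort
#: (32/58 subjects with 2 visits, 21/58 with 3, 3/58 with 4, 2/58 with 5).
DEFAULT_VISIT_DIST: dict[int, float] = {2: 32 / 58, 3: 21 / 58, 4: 3 / 58, 5: 2 / 58}

#: Gender mix approximating the published discovery cohort (41 M / 17 F).
DEFAULT_GENDER_P: dict[str, float] = {"M": 41 / 58, "F": 17 / 58}

DEFAULT_DX_P: dict[str, float] = {
    "BP": 0.30, "MDD": 0.25, "SZ": 0.20, "SZA": 0.15, "PTSD": 0.10}


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohorts.

    Effects are expressed in units of ``noise_sd`` so that ``state_effect=1``
    means a one-measurement-sd shift between low- and high-anxiety visits.
    """

    n_subjects_discovery: int = 60
    n_subjects_validation: int = 40
    n_subjects_test: int = 200
    visits_per_subject: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_VISIT_DIST))
    n_probesets: int = 2000
    n_state_markers: int = 20
    n_trait_markers: int = 20
    state_effect: float = 1.0
    severe_extra_effect: float = 0.5
    trait_effect: float = 1.0
    trait_log_hazard: float = math.log(2.0)
    base_hazard: float = 0.12
    noise_sd: float = 1.0
    subject_sd: float = 0.5
    detection_threshold: float = 6.0
    gender_p: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENDER_P))
    dx_p: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DX_P))
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_subjects_discovery, self.n_subjects_validation,
               self.n_subjects_test) < 1:
            raise SimulationError("every cohort needs at least one subject")
        if self.n_state_markers + self.n_trait_markers > self.n_probesets:
            raise SimulationError("more planted markers than probesets")
        for dist, name in ((self.visits_per_subject, "visits_per_subject"),
                           (self.gender_p, "gender_p"), (self.dx_p, "dx_p")):
            total = sum(dist.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise SimulationError(f"{name} probabilities sum to {total}, not 1")
        if any(v < 2 or v > 5 for v in self.visits_per_subject):
            raise SimulationError("visits_per_subject support must lie in 2..5")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be positive")


@dataclass
class SimTruth:
    """Planted-marker ground truth for recovery testing."""

    state_marker_ids: frozenset[str]
    trait_marker_ids: frozenset[str]
    directions: dict[str, str]  # marker -> 'increased'/'decreased' in high anxiety
    state_effect: float
    trait_effect: float
    trait_log_hazard: float
    probeset_ids: list[str]
    gene_map: dict[str, str]  # probeset -> gene symbol
    cohorts: dict[str, str]  # subject_id -> {'discovery','validation','test'}

    def cohort_of(self, record: VisitRecord) -> str:
        return self.cohorts[record.subject_id]


def _draw_visits(rng: np.random.Generator, dist: Mapping[int, float]) -> int:
    ks = sorted(dist)
    return int(rng.choice(ks, p=[dist[k] for k in ks]))


def _stai_for(rng: np.random.Generator, sas4: float, severe: bool) -> float:
    if severe:
        return float(rng.uniform(55.0, 80.0))
    # correlated with SAS-4 but noisy, mirroring the moderate published R=0.67
    return float(np.clip(0.55 * sas4 + 22.0 + rng.normal(0.0, 6.0), 20.0, 80.0))


def simulate_cohort(config: SimulationConfig,
                    ) -> tuple[ExpressionMatrix, list[VisitRecord], SimTruth]:
    """Generate the three cohorts, their expression, and the planted truth.

    Subject ids are prefixed ``D``/``V``/``T`` by cohort; use
    :func:`cohort_subset` to split. Identical configs (including seed)
    produce bit-identical output.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    (ss_markers, ss_baseline, ss_disc, ss_valid, ss_test,
     ss_noise, ss_hosp) = root.spawn(7)
    rng_markers = np.random.default_rng(ss_markers)
    rng_noise = np.random.default_rng(ss_noise)

    p = config.n_probesets
    probesets = [f"ps{i:05d}_at" for i in range(p)]
    gene_map = {ps: f"G{ps[2:7]}" for ps in probesets}

    planted = rng_markers.choice(
        p, size=config.n_state_markers + config.n_trait_markers, replace=False)
    state_idx = np.sort(planted[:config.n_state_markers])
    trait_idx = np.sort(planted[config.n_state_markers:])
    directions_arr = rng_markers.choice([1.0, -1.0], size=p)
    baseline = np.random.default_rng(ss_baseline).uniform(4.0, 10.0, size=p)

    state_mask = np.zeros(p, dtype=bool)
    state_mask[state_idx] = True
    trait_mask = np.zeros(p, dtype=bool)
    trait_mask[trait_idx] = True

    records: list[VisitRecord] = []
    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    cohorts: dict[str, str] = {}

    def expression_for(high: bool, severe: bool, subj_effect: np.ndarray,
                       trait_liability: float) -> np.ndarray:
        x = baseline + subj_effect
        shift = np.zeros(p)
        if high:
            shift[state_mask] = config.state_effect
        if severe:
            shift[state_mask] += config.severe_extra_effect
        x = x + directions_arr * shift * config.noise_sd
        x = x + (directions_arr * trait_mask * config.trait_effect
                 * config.noise_sd * trait_liability)
        return x + rng_noise.normal(0.0, config.noise_sd, size=p)

    def demographics(rng: np.random.Generator) -> tuple[str, str]:
        g = str(rng.choice(sorted(config.gender_p),
                           p=[config.gender_p[k] for k in sorted(config.gender_p)]))
        d = str(rng.choice(sorted(config.dx_p),
                           p=[config.dx_p[k] for k in sorted(config.dx_p)]))
        return g, d

    # --- discovery: alternating LOW/HIGH trajectories -----------------------
    rng = np.random.default_rng(ss_disc)
    for s in range(config.n_subjects_discovery):
        sid = f"D{s:04d}"
        cohorts[sid] = "discovery"
        gender, dx = demographics(rng)
        n_visits = _draw_visits(rng, config.visits_per_subject)
        subj_effect = rng.normal(0.0, config.subject_sd, size=p)
        liability = float(rng.normal())
        start_high = bool(rng.integers(2))
        t = 0.0
        for v in range(n_visits):
            high = (v % 2 == 0) == start_high
            sas4 = float(rng.uniform(60.0, 95.0) if high else rng.uniform(5.0, 40.0))
            stai = _stai_for(rng, sas4, severe=False)
            sample = f"{sid}:V{v + 1}"
            records.append(VisitRecord(
                sample_id=sample, subject_id=sid, visit_index=v + 1,
                gender=gender, diagnosis=dx, sas4=sas4, visit_time=t,
                stai_state=stai))
            columns.append(expression_for(high, False, subj_effect, liability))
            sample_ids.append(sample)
            t += float(rng.uniform(0.25, 0.5))

    # --- validation: single severe-anxiety visit per subject ----------------
    rng = np.random.default_rng(ss_valid)
    for s in range(config.n_subjects_validation):
        sid = f"V{s:04d}"
        cohorts[sid] = "validation"
        gender, dx = demographics(rng)
        subj_effect = rng.normal(0.0, config.subject_sd, size=p)
        liability = float(rng.normal())
        sas4 = float(rng.uniform(60.0, 95.0))
        stai = _stai_for(rng, sas4, severe=True)
        sample = f"{sid}:V1"
        records.append(VisitRecord(
            sample_id=sample, subject_id=sid, visit_index=1, gender=gender,
            diagnosis=dx, sas4=sas4, visit_time=0.0, stai_state=stai))
        columns.append(expression_for(True, True, subj_effect, liability))
        sample_ids.append(sample)

    # --- test: free-ranging anxiety, follow-up outcomes ---------------------
    rng = np.random.default_rng(ss_test)
    rng_hosp = np.random.default_rng(ss_hosp)
    test_meta = []
    for s in range(config.n_subjects_test):
        sid = f"T{s:04d}"
        cohorts[sid] = "test"
        gender, dx = demographics(rng)
        n_visits = _draw_visits(rng, config.visits_per_subject)
        subj_effect = rng.normal(0.0, config.subject_sd, size=p)
        liability = float(rng.normal())
        t = 0.0
        visit_rows = []
        for v in range(n_visits):
            sas4 = float(rng.uniform(0.0, 100.0))
            high = sas4 >= 60.0
            stai = _stai_for(rng, sas4, severe=False)
            sample = f"{sid}:V{v + 1}"
            visit_rows.append(dict(
                sample_id=sample, subject_id=sid, visit_index=v + 1,
                gender=gender, diagnosis=dx, sas4=sas4, visit_time=t,
                stai_state=stai))
            columns.append(expression_for(high, False, subj_effect, liability))
            sample_ids.append(sample)
            t += float(rng.uniform(0.25, 0.5))
        test_meta.append((sid, visit_rows, liability))

    # hospitalization outcomes: hazard log-linear in mean z-scored
    # trait-marker expression (direction-aligned via the planted liability)
    values = pd.DataFrame(np.column_stack(columns), index=probesets,
                          columns=sample_ids)
    test_samples = [row["sample_id"] for _, rows, _ in test_meta for row in rows]
    trait_block = values.loc[np.array(probesets)[trait_mask], test_samples]
    aligned = trait_block.mul(directions_arr[trait_mask], axis=0)
    subj_of = {row["sample_id"]: sid for sid, rows, _ in test_meta for row in rows}
    subj_mean = aligned.mean(axis=0).groupby(subj_of).mean()
    zmean = (subj_mean - subj_mean.mean()) / subj_mean.std(ddof=1) \
        if len(subj_mean) > 1 and subj_mean.std(ddof=1) > 0 else subj_mean * 0.0

    for sid, visit_rows, _ in test_meta:
        hazard = config.base_hazard * math.exp(
            config.trait_log_hazard * float(zmean[sid]))
        event_time = float(rng_hosp.exponential(1.0 / hazard))
        censor_abs = float(rng_hosp.uniform(2.0, 12.0))
        event = event_time <= censor_abs
        for row in visit_rows:
            v = row.pop("visit_time")
            horizon = min(event_time, censor_abs)
            remaining = max(horizon - v, 0.01)
            records.append(VisitRecord(
                visit_time=v,
                followup_first_year_hosp=bool(event and event_time - v <= 1.0),
                followup_any_future_hosp=bool(event),
                time_to_first_hosp=remaining if event else None,
                censor_time=remaining,
                **row))

    detection = pd.DataFrame(values.to_numpy() > config.detection_threshold,
                             index=values.index, columns=values.columns)
    matrix = ExpressionMatrix(values, detection)
    truth = SimTruth(
        state_marker_ids=frozenset(np.array(probesets)[state_mask]),
        trait_marker_ids=frozenset(np.array(probesets)[trait_mask]),
        directions={ps: ("increased" if directions_arr[i] > 0 else "decreased")
                    for i, ps in enumerate(probesets)},
        state_effect=config.state_effect, trait_effect=config.trait_effect,
        trait_log_hazard=config.trait_log_hazard,
        probeset_ids=probesets, gene_map=gene_map, cohorts=cohorts)
    return matrix, records, truth


def cohort_subset(matrix: ExpressionMatrix, records: Sequence[VisitRecord],
                  truth: SimTruth, which: str,
                  ) -> tuple[ExpressionMatrix, list[VisitRecord]]:
    """Extract one cohort ('discovery', 'validation', or 'test')."""
    recs = [r for r in records if truth.cohort_of(r) == which]
    if not recs:
        raise SimulationError(f"no records in cohort {which!r}")
    sub = matrix.subset_samples([r.sample_id for r in recs])
    return sub, recs


EVIDENCE_CATEGORIES = [
    ("human", "genetic"), ("human", "expression_brain"),
    ("human", "expression_peripheral"),
    ("animal", "genetic"), ("animal", "expression_brain"),
    ("animal", "expression_peripheral"),
]


def simulate_evidence_table(truth: SimTruth, sensitivity: float,
                            false_positive_rate: float, seed: int,
                            weight: float = 2.0) -> pd.DataFrame:
    """Literature-evidence stand-in for convergent-evidence prioritization.

    Each planted marker's gene receives each of the six evidence categories
    independently with probability ``sensitivity``; null genes with
    probability ``false_positive_rate``. Weights default to the per-category
    cap so a fully annotated gene saturates the 12-point score.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= false_positive_rate <= 1.0):
        raise SimulationError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    planted = truth.state_marker_ids | truth.trait_marker_ids
    rows = []
    for ps in truth.probeset_ids:
        rate = sensitivity if ps in planted else false_positive_rate
        for species, kind in EVIDENCE_CATEGORIES:
            if rng.random() < rate:
                rows.append({"gene_symbol": truth.gene_map[ps],
                             "species": species, "evidence_kind": kind,
                             "weight": weight})
    return pd.DataFrame(rows,
                        columns=["gene_symbol", "species", "evidence_kind", "weight"])
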