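"""Step 4 — stratified state and trait prediction in an independent cohort.

Top candidates are tested for clinical utility on four targets: high
anxiety state (SAS-4 >= 60), clinically severe anxiety state (SAS-4 >= 60
with STAI State >= 55), hospitalization with anxiety within the first year
of follow-up, and all future hospitalizations with anxiety. State and
first-year targets are scored by ROC AUC (equivalently the Mann-Whitney U
statistic scaled to [0, 1], one-sided in the discovery direction); the
all-future target by a univariate Cox proportional-hazards fit, reporting
the hazard ratio per 1-sd increase of the marker.

Each target is evaluated in all subjects, per gender, and per gender x
diagnosis (with schizophrenia and schizoaffective also pooled as
PSYCHOSIS), both cross-sectionally (visit-level values) and longitudinally
(a combined feature integrating last level, maximum level, slope into the
most recent visit, and maximum slope). Per-category points follow a
maximum rule: 3 when any all-subject result is significant, else 2 for any
gender stratum, else 1 for any gender-by-diagnosis stratum, else 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (ExpressionMatrix, VisitRecord, label_state, StateLabel,
                     stratum_of, GENDERS, DIAGNOSES)

log = logging.getLogger(__name__)

STEP4_TARGETS = ("state_sas4", "state_stai", "hosp_first_year", "hosp_all_future")

#: Number of candidate biomarkers behind the default Bonferroni correction.
DEFAULT_N_BIOMARKERS = 95

MIN_CLASS_N = 2    # positives and negatives required for an AUC stratum
MIN_EVENTS = 3     # events required for a proportional-hazards stratum


@dataclass(frozen=True)
class LongitudinalFeatures:
    """Trajectory summary of one subject's marker levels over visits."""

    last_level: float
    max_level: float
    last_slope: float
    max_slope: float


@dataclass(frozen=True)
class HazardResult:
    ratio: float
    p: float
    converged: bool = True


def longitudinal_features(times: Sequence[float],
                          levels: Sequence[float]) -> LongitudinalFeatures:
    """Level/slope features from >=2 visits with strictly increasing times."""
    t = np.asarray(times, dtype=float)
    x = np.asarray(levels, dtype=float)
    if t.size < 2:
        raise ValueError("longitudinal features need >=2 visits")
    if np.any(np.diff(t) <= 0):
        raise ValueError("visit times must be strictly increasing")
    slopes = np.diff(x) / np.diff(t)
    return LongitudinalFeatures(
        last_level=float(x[-1]), max_level=float(x.max()),
        last_slope=float(slopes[-1]), max_slope=float(slopes.max()))


def combine_longitudinal(features: pd.DataFrame) -> pd.Series:
    """Combined longitudinal score: mean of the four per-subject features,
    each z-scored across the subjects of the evaluation stratum."""
    z = features.astype(float).copy()
    for col in z.columns:
        sd = z[col].std(ddof=1)
        z[col] = (z[col] - z[col].mean()) / sd if sd and sd > 0 else 0.0
    return z.mean(axis=1)


def auc_predict(values: Sequence[float], labels: Sequence[bool],
                direction: str = "increased",
                alternative: str = "greater") -> tuple[float, float]:
    """ROC AUC and Mann-Whitney significance for a binary outcome.

    Values are oriented so the discovery direction predicts the positive
    class (decreased markers are negated). The AUC equals the Mann-Whitney
    U statistic over positive-negative pairs with ties counted 1/2; the
    p-value is the one-sided normal approximation with tie correction.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if direction == "decreased":
        x = -x
    elif direction != "increased":
        raise ValueError(f"unknown direction {direction!r}")
    pos, neg = x[y], x[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both classes non-empty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-tied inputs: p is 1 by convention
        res = stats.mannwhitneyu(pos, neg, alternative=alternative,
                                 method="asymptotic")
    auc = float(res.statistic) / (pos.size * neg.size)
    return auc, float(res.pvalue)


def hazard_predict(values: Sequence[float], durations: Sequence[float],
                   events: Sequence[bool]) -> HazardResult:
    """Univariate Cox proportional-hazards fit of time-to-event on a marker.

    The marker is z-scored (sample sd) so the ratio is per 1-sd increase;
    the p-value is the Wald test. A constant marker or zero events is a
    hard error; non-convergence returns a flagged result that callers
    exclude from scoring.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    x = np.asarray(values, dtype=float)
    d = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if e.sum() < 1:
        raise ValueError("proportional-hazards fit needs at least one event")
    sd = x.std(ddof=1)
    if not sd > 0:
        raise ValueError("marker is constant; hazard ratio not identifiable")
    frame = pd.DataFrame({"marker": (x - x.mean()) / sd, "T": d, "E": e.astype(int)})
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(frame, duration_col="T", event_col="E")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return HazardResult(float("nan"), float("nan"), converged=False)
    coef = float(fitter.params_["marker"])
    p = float(fitter.summary.loc["marker", "p"])
    return HazardResult(float(np.exp(coef)), p, converged=True)


def bonferroni_flag(p: float, n_biomarkers: int = DEFAULT_N_BIOMARKERS) -> bool:
    """Whether p survives Bonferroni correction across the tested panel
    (strict inequality)."""
    if n_biomarkers < 1:
        raise ValueError("n_biomarkers must be >=1")
    return p < 0.05 / n_biomarkers


def stratum_level(stratum: str) -> int:
    """Points value of a stratum class: ALL=3, gender=2, gender-dx=1."""
    if stratum == "ALL":
        return 3
    if stratum in GENDERS:
        return 2
    return 1


def step4_points(results: Iterable[tuple[str, float]] | pd.DataFrame,
                 alpha: float = 0.05) -> int:
    """Per-category points from (stratum, p) results under the maximum rule.

    3 if any all-subject result is significant, else 2 for any gender
    stratum, else 1 for any gender-by-diagnosis stratum, else 0. The rule
    takes the maximum, never the sum.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if isinstance(results, pd.DataFrame):
        pairs = list(zip(results["stratum"], results["p"]))
    else:
        pairs = list(results)
    best = 0
    for stratum, p in pairs:
        if p is not None and np.isfinite(p) and p < alpha:
            best = max(best, stratum_level(str(stratum)))
    return best


# ---------------------------------------------------------------------------
# Cohort-level evaluation


def _strata_members(records: Sequence[VisitRecord]) -> dict[str, list[str]]:
    """Sample ids per evaluation stratum (ALL, genders, gender-dx incl.
    pooled PSYCHOSIS)."""
    members: dict[str, list[str]] = {"ALL": []}
    for g in GENDERS:
        members[g] = []
    for rec in records:
        members["ALL"].append(rec.sample_id)
        members[rec.gender].append(rec.sample_id)
        members.setdefault(stratum_of(rec), []).append(rec.sample_id)
        if rec.diagnosis in ("SZ", "SZA"):
            members.setdefault(stratum_of(rec, pool_psychosis=True),
                               []).append(rec.sample_id)
    return members


def _target_labels(records: Sequence[VisitRecord], target: str,
                   ) -> dict[str, bool]:
    """Visit-level positive-class labels; visits with missing data drop out."""
    labels: dict[str, bool] = {}
    for rec in records:
        if target == "state_sas4":
            labels[rec.sample_id] = rec.sas4 >= 60.0
        elif target == "state_stai":
            labels[rec.sample_id] = label_state(rec) is StateLabel.SEVERE
        elif target == "hosp_first_year":
            if rec.followup_first_year_hosp is not None:
                labels[rec.sample_id] = rec.followup_first_year_hosp
        else:
            raise ValueError(f"no AUC labels for target {target!r}")
    return labels


def test_candidates(candidates: pd.DataFrame, test_z: ExpressionMatrix,
                    records: Sequence[VisitRecord], alpha: float = 0.05,
                    n_biomarkers: int | None = None,
                    longitudinal: bool = True) -> pd.DataFrame:
    """Evaluate every candidate on every target, stratum, and mode.

    ``candidates`` is indexed by probeset with a ``direction`` column;
    ``test_z`` is the stratified z-scored test-cohort matrix. Returns a tidy
    frame with one row per probeset x target x stratum x mode, with columns
    ``statistic`` (AUC or hazard ratio), ``p``, ``n_pos``, ``n_total`` and
    ``bonferroni``. Strata with fewer than two observations per class (AUC)
    or three events (hazards) are skipped.
    """
    n_bonf = n_biomarkers if n_biomarkers is not None else len(candidates)
    rec_by_id = {r.sample_id: r for r in records}
    members = _strata_members(records)
    rows: list[dict] = []

    for target in ("state_sas4", "state_stai", "hosp_first_year"):
        labels = _target_labels(records, target)
        for stratum, samples in members.items():
            usable = [s for s in samples if s in labels]
            y = np.array([labels[s] for s in usable])
            if y.sum() < MIN_CLASS_N or (~y).sum() < MIN_CLASS_N:
                log.debug("skipping %s/%s: class too small", target, stratum)
                continue
            block = test_z.values[usable]
            for ps, direction in candidates["direction"].items():
                auc, p = auc_predict(block.loc[ps].to_numpy(), y, direction)
                rows.append(dict(probeset=ps, target=target, stratum=stratum,
                                 mode="cross_sectional", statistic=auc, p=p,
                                 n_pos=int(y.sum()), n_total=int(y.size)))
            if longitudinal:
                rows.extend(_longitudinal_rows(
                    candidates, test_z, rec_by_id, usable, labels, target,
                    stratum))

    rows.extend(_hazard_rows(candidates, test_z, rec_by_id, members))

    result = pd.DataFrame(rows, columns=["probeset", "target", "stratum", "mode",
                                         "statistic", "p", "n_pos", "n_total"])
    result["bonferroni"] = [bonferroni_flag(p, n_bonf) if np.isfinite(p) else False
                            for p in result["p"]]
    return result


def _longitudinal_rows(candidates, test_z, rec_by_id, usable, labels, target,
                       stratum) -> list[dict]:
    """Subject-level longitudinal AUC rows for one target/stratum."""
    by_subject: dict[str, list[VisitRecord]] = {}
    for s in usable:
        rec = rec_by_id[s]
        by_subject.setdefault(rec.subject_id, []).append(rec)
    multi = {sid: sorted(recs, key=lambda r: r.visit_index)
             for sid, recs in by_subject.items() if len(recs) >= 2}
    if not multi:
        return []
    # positive class = label at the most recent usable visit
    subj_label = {sid: labels[recs[-1].sample_id] for sid, recs in multi.items()}
    y = np.array([subj_label[sid] for sid in multi])
    if y.sum() < MIN_CLASS_N or (~y).sum() < MIN_CLASS_N:
        return []
    rows = []
    times = {sid: [r.visit_time if r.visit_time is not None else i
                   for i, r in enumerate(recs)] for sid, recs in multi.items()}
    for ps, direction in candidates["direction"].items():
        feats = {}
        for sid, recs in multi.items():
            levels = [float(test_z.values.at[ps, r.sample_id]) for r in recs]
            f = longitudinal_features(times[sid], levels)
            feats[sid] = [f.last_level, f.max_level, f.last_slope, f.max_slope]
        frame = pd.DataFrame.from_dict(
            feats, orient="index",
            columns=["last_level", "max_level", "last_slope", "max_slope"])
        combined = combine_longitudinal(frame).loc[list(multi)]
        auc, p = auc_predict(combined.to_numpy(), y, direction)
        rows.append(dict(probeset=ps, target=target, stratum=stratum,
                         mode="longitudinal", statistic=auc, p=p,
                         n_pos=int(y.sum()), n_total=int(y.size)))
    return rows


def _hazard_rows(candidates, test_z, rec_by_id, members) -> list[dict]:
    rows = []
    for stratum, samples in members.items():
        usable = [s for s in samples
                  if rec_by_id[s].censor_time is not None
                  and rec_by_id[s].followup_any_future_hosp is not None]
        if not usable:
            continue
        events = np.array([rec_by_id[s].followup_any_future_hosp for s in usable])
        if events.sum() < MIN_EVENTS:
            log.debug("skipping hosp_all_future/%s: <%d events", stratum, MIN_EVENTS)
            continue
        durations = np.array([rec_by_id[s].censor_time for s in usable])
        block = test_z.values[usable]
        for ps, direction in candidates["direction"].items():
            x = block.loc[ps].to_numpy()
            if direction == "decreased":
                x = -x
            if not x.std(ddof=1) > 0:
                continue
            res = hazard_predict(x, durations, events)
            if not res.converged:
                continue
            rows.append(dict(probeset=ps, target="hosp_all_future",
                             stratum=stratum, mode="cross_sectional",
                             statistic=res.ratio, p=res.p,
                             n_pos=int(events.sum()), n_total=int(events.size)))
    return rows


def step4_summary(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-probeset points for each of the four prediction categories."""
    probesets = sorted(results["probeset"].unique())
    out = pd.DataFrame(index=pd.Index(probesets, name="probeset"),
                       columns=list(STEP4_TARGETS), data=0)
    for (ps, target), grp in results.groupby(["probeset", "target"]):
        out.at[ps, target] = step4_points(
            list(zip(grp["stratum"], grp["p"])), alpha=alpha)
    return out.astype(int)
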