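"""Cohort data model, file IO, state labeling, and stratified normalization.

The pipeline operates on two joined objects: an :class:`ExpressionMatrix`
(probesets x visit samples, array-normalized values, optional Present/Absent
detection calls) and a list of :class:`VisitRecord` (one subject-visit with
phenotype scores and follow-up outcomes). Expression is z-scored per probeset
within gender x diagnosis strata before cohorts are combined, so that
demographic and medication effects are normalized out.

Anxiety state at a visit is labeled from the SAS-4 visual analog scale
(0-100): LOW at <=40, HIGH at >=60, and SEVERE when a HIGH visit also has an
STAI State score >=55 (clinically severe anxiety). Scores strictly between
the cutoffs are INTERMEDIATE and take no part in discovery pairing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GENDERS = ("M", "F")
DIAGNOSES = ("BP", "MDD", "SZ", "SZA", "PTSD")

#: SZ and SZA pooled for stratified prediction reporting.
PSYCHOSIS = ("SZ", "SZA")

SAS4_LOW = 40.0
SAS4_HIGH = 60.0
STAI_SEVERE = 55.0

METADATA_COLUMNS = [
    "sample_id", "subject_id", "visit_index", "visit_time", "gender",
    "diagnosis", "sas4", "stai_state", "followup_first_year_hosp",
    "followup_any_future_hosp", "time_to_first_hosp", "censor_time",
]


class StateLabel(str, Enum):
    LOW = "LOW"
    HIGH = "HIGH"
    SEVERE = "SEVERE"
    INTERMEDIATE = "INTERMEDIATE"


class CohortError(ValueError):
    """Raised for malformed cohort inputs."""


@dataclass(frozen=True)
class VisitRecord:
    """One subject-visit: identity, phenotype scores, follow-up outcomes.

    ``visit_time`` is in decimal years from the subject's first visit;
    ``time_to_first_hosp`` and ``censor_time`` are decimal years from this
    visit. Missing phenotype fields are ``None`` and are never imputed.
    """

    sample_id: str
    subject_id: str
    visit_index: int
    gender: str
    diagnosis: str
    sas4: float
    visit_time: float | None = None
    stai_state: float | None = None
    followup_first_year_hosp: bool | None = None
    followup_any_future_hosp: bool | None = None
    time_to_first_hosp: float | None = None
    censor_time: float | None = None

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise CohortError(f"unknown gender {self.gender!r} for {self.sample_id}")
        if self.diagnosis not in DIAGNOSES:
            raise CohortError(
                f"unknown diagnosis {self.diagnosis!r} for {self.sample_id}")
        if self.visit_index < 1:
            raise CohortError(f"visit_index must be >=1 ({self.sample_id})")
        # NaN marks a missing score; state labeling rejects it later
        if not math.isnan(self.sas4) and not (0.0 <= self.sas4 <= 100.0):
            raise CohortError(f"sas4 out of [0,100] for {self.sample_id}: {self.sas4}")
        if (self.time_to_first_hosp is not None and self.censor_time is not None
                and self.time_to_first_hosp > self.censor_time + 1e-12):
            raise CohortError(
                f"time_to_first_hosp exceeds censor_time for {self.sample_id}")


@dataclass
class ExpressionMatrix:
    """Probesets x samples matrix of normalized expression values.

    ``values`` is indexed by probeset id with sample ids as columns;
    ``detection`` (optional) holds boolean Present calls with identical layout.
    """

    values: pd.DataFrame
    detection: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise CohortError(f"duplicate probeset ids: {sorted(dupes)[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise CohortError("expression values must be finite")
        if self.detection is not None:
            if (list(self.detection.index) != list(self.values.index)
                    or list(self.detection.columns) != list(self.values.columns)):
                raise CohortError("detection calls must mirror the value layout")

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        det = self.detection[list(sample_ids)] if self.detection is not None else None
        return ExpressionMatrix(self.values[list(sample_ids)], det)


def label_state(record: VisitRecord,
                sas4_low: float = SAS4_LOW,
                sas4_high: float = SAS4_HIGH,
                stai_severe: float = STAI_SEVERE) -> StateLabel:
    """Anxiety state at a visit, from inclusive SAS-4/STAI thresholds.

    SEVERE requires both SAS-4 >= ``sas4_high`` and STAI State >=
    ``stai_severe``; a high-SAS-4 visit with missing STAI is HIGH, never
    SEVERE.
    """
    sas4 = record.sas4
    if sas4 is None or (isinstance(sas4, float) and math.isnan(sas4)):
        raise CohortError(f"missing sas4 for {record.sample_id}")
    if sas4 <= sas4_low:
        return StateLabel.LOW
    if sas4 >= sas4_high:
        if record.stai_state is not None and record.stai_state >= stai_severe:
            return StateLabel.SEVERE
        return StateLabel.HIGH
    return StateLabel.INTERMEDIATE


def stratum_of(record: VisitRecord, pool_psychosis: bool = False) -> str:
    """Gender x diagnosis stratum label, e.g. ``'M-BP'``.

    With ``pool_psychosis`` SZ and SZA map to the combined PSYCHOSIS group
    (used only when reporting stratified predictions, never for
    normalization by default).
    """
    dx = record.diagnosis
    if pool_psychosis and dx in PSYCHOSIS:
        dx = "PSYCHOSIS"
    return f"{record.gender}-{dx}"


# ---------------------------------------------------------------------------
# File IO


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip", **kwargs)


def _opt_float(x) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)) or pd.isna(x):
        return None
    return float(x)


def _opt_bool(x) -> bool | None:
    if x is None or pd.isna(x):
        return None
    if isinstance(x, str):
        return x.strip().lower() in ("1", "true", "t", "yes")
    return bool(x)


def _records_from_frame(meta: pd.DataFrame) -> list[VisitRecord]:
    records = []
    for _, row in meta.iterrows():
        records.append(VisitRecord(
            sample_id=str(row["sample_id"]),
            subject_id=str(row["subject_id"]),
            visit_index=int(row["visit_index"]),
            gender=str(row["gender"]),
            diagnosis=str(row["diagnosis"]),
            sas4=float(row["sas4"]),
            visit_time=_opt_float(row.get("visit_time")),
            stai_state=_opt_float(row.get("stai_state")),
            followup_first_year_hosp=_opt_bool(row.get("followup_first_year_hosp")),
            followup_any_future_hosp=_opt_bool(row.get("followup_any_future_hosp")),
            time_to_first_hosp=_opt_float(row.get("time_to_first_hosp")),
            censor_time=_opt_float(row.get("censor_time")),
        ))
    seen: dict[tuple[str, int], str] = {}
    for rec in records:
        key = (rec.subject_id, rec.visit_index)
        if key in seen:
            raise CohortError(
                f"duplicate visit_index {rec.visit_index} for subject "
                f"{rec.subject_id} (samples {seen[key]}, {rec.sample_id})")
        seen[key] = rec.sample_id
    return records


def read_cohort(expression_path: str | Path, metadata_path: str | Path,
                detection_path: str | Path | None = None,
                ) -> tuple[ExpressionMatrix, list[VisitRecord]]:
    """Read and join an expression matrix with its visit metadata.

    The expression file has probeset ids in the first column and sample ids
    as the remaining headers; the metadata file has one row per sample with
    the :class:`VisitRecord` fields. Sample ids must match one-to-one.
    """
    expr = _read_table(expression_path, index_col=0)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)

    bad = [(str(i), str(c)) for c in expr.columns
           for i, v in expr[c].items()
           if not isinstance(v, (int, float, np.integer, np.floating))
           or (isinstance(v, float) and math.isnan(v))]
    if not bad:
        try:
            expr = expr.astype(float)
        except (TypeError, ValueError):
            bad = [("?", "?")]
    if bad or expr.isna().any().any():
        if not bad:
            where = expr.isna().stack()
            bad = [tuple(map(str, idx)) for idx in where[where].index[:5]]
        raise CohortError(f"non-numeric expression cells at {bad[:5]}")

    meta = _read_table(metadata_path, dtype={"sample_id": str, "subject_id": str})
    missing_cols = {"sample_id", "subject_id", "visit_index", "gender",
                    "diagnosis", "sas4"} - set(meta.columns)
    if missing_cols:
        raise CohortError(f"metadata missing columns: {sorted(missing_cols)}")

    meta_ids = list(meta["sample_id"].astype(str))
    expr_ids = list(expr.columns)
    only_meta = sorted(set(meta_ids) - set(expr_ids))
    only_expr = sorted(set(expr_ids) - set(meta_ids))
    if only_meta or only_expr:
        raise CohortError(
            "sample ids do not match between expression and metadata: "
            f"metadata-only={only_meta[:10]}, expression-only={only_expr[:10]}")
    if len(set(meta_ids)) != len(meta_ids):
        raise CohortError("duplicate sample ids in metadata")

    detection = None
    if detection_path is not None:
        det = _read_table(detection_path, index_col=0)
        det.index = det.index.astype(str)
        det.columns = det.columns.astype(str)
        det = det.reindex(index=expr.index, columns=expr.columns)
        if det.isna().any().any():
            raise CohortError("detection-call file layout does not match expression")
        detection = det.map(lambda v: str(v).strip().upper() in ("P", "TRUE", "1"))

    records = _records_from_frame(meta)
    # order records to match expression columns
    by_id = {r.sample_id: r for r in records}
    records = [by_id[s] for s in expr_ids]
    return ExpressionMatrix(expr, detection), records


def records_to_frame(records: Iterable[VisitRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in METADATA_COLUMNS})
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def write_cohort(matrix: ExpressionMatrix, records: Sequence[VisitRecord],
                 expression_path: str | Path, metadata_path: str | Path,
                 detection_path: str | Path | None = None) -> None:
    """Write a cohort in the formats :func:`read_cohort` accepts."""
    sep = "\t" if str(expression_path).endswith((".tsv", ".txt")) else ","
    # %.17g guarantees exact round-trip of double-precision values
    matrix.values.to_csv(expression_path, sep=sep, index_label="probeset",
                         float_format="%.17g")
    msep = "\t" if str(metadata_path).endswith((".tsv", ".txt")) else ","
    records_to_frame(records).to_csv(metadata_path, sep=msep, index=False,
                                     float_format="%.17g")
    if detection_path is not None and matrix.detection is not None:
        dsep = "\t" if str(detection_path).endswith((".tsv", ".txt")) else ","
        calls = matrix.detection.map(lambda b: "P" if b else "A")
        calls.to_csv(detection_path, sep=dsep, index_label="probeset")


# ---------------------------------------------------------------------------
# Stratified z-scoring


class StratumNormalizer:
    """Per-probeset z-scoring within gender x diagnosis strata.

    Fit stores per-stratum means and sample standard deviations (n-1
    denominator); transform applies them, so a later cohort can be
    normalized with frozen discovery-cohort parameters (out-of-sample).
    Probesets with zero variance within a stratum are set to 0 with a
    warning. Unseen strata at transform time fall back to the pooled
    fit-cohort parameters.
    """

    def __init__(self, strata: Callable[[VisitRecord], str] | None = None):
        self.strata = strata or stratum_of
        self.params_: dict[str, tuple[pd.Series, pd.Series]] = {}
        self.pooled_: tuple[pd.Series, pd.Series] | None = None

    def _groups(self, records: Sequence[VisitRecord]) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for rec in records:
            groups.setdefault(self.strata(rec), []).append(rec.sample_id)
        return groups

    def fit(self, matrix: ExpressionMatrix,
            records: Sequence[VisitRecord]) -> "StratumNormalizer":
        for name, samples in self._groups(records).items():
            if len(samples) < 2:
                raise CohortError(
                    f"stratum {name!r} has {len(samples)} sample(s); "
                    "need >=2 for z-scoring")
            block = matrix.values[samples]
            self.params_[name] = (block.mean(axis=1), block.std(axis=1, ddof=1))
        pooled = matrix.values
        self.pooled_ = (pooled.mean(axis=1), pooled.std(axis=1, ddof=1))
        return self

    def transform(self, matrix: ExpressionMatrix,
                  records: Sequence[VisitRecord]) -> ExpressionMatrix:
        if self.pooled_ is None:
            raise RuntimeError("normalizer is not fitted")
        out = pd.DataFrame(index=matrix.values.index, columns=matrix.values.columns,
                           dtype=float)
        warned = False
        for name, samples in self._groups(records).items():
            mean, sd = self.params_.get(name, self.pooled_)
            block = matrix.values[samples]
            z = block.sub(mean, axis=0).div(sd.where(sd > 0), axis=0)
            flat = sd == 0
            if flat.any():
                z.loc[flat] = 0.0
                if not warned:
                    warnings.warn(
                        f"{int(flat.sum())} zero-variance probeset(s) in stratum "
                        f"{name!r}; their z-scores set to 0", stacklevel=2)
                    warned = True
            out[samples] = z
        return ExpressionMatrix(out.fillna(0.0), matrix.detection)


def zscore_by_stratum(matrix: ExpressionMatrix, records: Sequence[VisitRecord],
                      strata: Callable[[VisitRecord], str] | None = None,
                      ) -> ExpressionMatrix:
    """Fit-and-apply stratified z-scoring on one cohort.

    Within each stratum every probeset ends with sample mean 0 and sample
    standard deviation 1 (ddof=1); the strata are then reassembled in the
    original sample order.
    """
    return StratumNormalizer(strata).fit(matrix, records).transform(matrix, records)
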