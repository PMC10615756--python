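"""Step 3 — out-of-sample validation in clinically severe anxiety.

Each candidate biomarker is tested for a stepwise change of group means
across three groups of z-scored expression: low-anxiety discovery visits,
high-anxiety discovery visits, and severe-anxiety validation visits. The
ordering must be strictly monotone in the candidate's discovery direction.
Significance across the three groups comes from one-way fixed-effects
ANOVA, with visits as the unit of observation. Points: 0 when not
stepwise; 2 for a stepwise change that is not nominally significant; 4
when nominally significant (p < 0.05); 6 when surviving Bonferroni
correction for the number of candidates tested.

The severe-anxiety cohort is z-scored with the discovery cohort's frozen
stratum parameters, so validation stays out-of-sample. CFE3 is the running
total of the first three steps (maximum 24); candidates with CFE3 >= 8
(one third of the maximum) are carried into predictive testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (ExpressionMatrix, StateLabel, StratumNormalizer,
                     VisitRecord, label_state)

CFE3_GATE = 8.0
CFE3_MAX = 24.0


@dataclass(frozen=True)
class ValidationResult:
    probeset_id: str
    stepwise: bool
    anova_p: float
    validation_points: int


def stepwise_change(low_mean: float, high_mean: float, severe_mean: float,
                    direction: str) -> bool:
    """Strictly monotone ordering of the three group means.

    Increased markers must rise low < high < severe; decreased markers must
    fall low > high > severe. Ties fail (on z-scored data exact ties are
    measure-zero).
    """
    if direction == "increased":
        return low_mean < high_mean < severe_mean
    if direction == "decreased":
        return low_mean > high_mean > severe_mean
    raise ValueError(f"unknown direction {direction!r}")


def anova_p(groups: Sequence[np.ndarray]) -> float:
    """One-way fixed-effects ANOVA p-value across groups of observations."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"ANOVA group {i} has n={g.size}; need >=2")
    stat, p = stats.f_oneway(*arrays)
    if np.isnan(p):  # zero within-group variance
        return 1.0 if np.isclose(stat if not np.isnan(stat) else 0.0, 0.0) else 0.0
    return float(p)


def validation_points(stepwise: bool, p: float, n_candidates: int,
                      alpha: float = 0.05, bonferroni_tier: bool = True) -> int:
    """Map a (stepwise, ANOVA p) pair onto 0/2/4/6 validation points.

    The 6-point Bonferroni tier can be disabled (capping at 4) for strict
    agreement with published score tables, none of which exhibit it.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError("p must lie in (0, 1]")
    if n_candidates < 1:
        raise ValueError("n_candidates must be >=1")
    if not stepwise:
        return 0
    if p >= alpha:
        return 2
    if p >= alpha / n_candidates or not bonferroni_tier:
        return 4
    return 6


def cfe3_score(discovery_points: float, cfg_points: float,
               validation_points: float) -> float:
    """Sum of the first three step scores (maximum 24)."""
    if not (0 <= discovery_points <= 6):
        raise ValueError("discovery points out of range 0..6")
    if not (0 <= cfg_points <= 12):
        raise ValueError("evidence points out of range 0..12")
    if not (0 <= validation_points <= 6):
        raise ValueError("validation points out of range 0..6")
    return float(discovery_points + cfg_points + validation_points)


def validate_candidates(candidates: pd.DataFrame,
                        discovery_z: ExpressionMatrix,
                        discovery_records: Sequence[VisitRecord],
                        validation_matrix: ExpressionMatrix,
                        validation_records: Sequence[VisitRecord],
                        normalizer: StratumNormalizer,
                        alpha: float = 0.05,
                        bonferroni_tier: bool = True) -> pd.DataFrame:
    """Run the stepwise/ANOVA validation over a candidate table.

    ``candidates`` is indexed by probeset with ``direction``,
    ``internal_points`` and ``cfg_points`` columns (the Step-2 output).
    ``discovery_z`` is the z-scored discovery matrix; the validation cohort
    is transformed with the discovery-fitted ``normalizer``. Returns the
    candidate frame extended with ``stepwise, anova_p, validation_points,
    cfe3``.
    """
    labels = {r.sample_id: label_state(r) for r in discovery_records}
    low_ids = [s for s, l in labels.items() if l is StateLabel.LOW]
    high_ids = [s for s, l in labels.items()
                if l in (StateLabel.HIGH, StateLabel.SEVERE)]
    severe_ids = [r.sample_id for r in validation_records
                  if label_state(r) is StateLabel.SEVERE]
    if min(len(low_ids), len(high_ids), len(severe_ids)) < 2:
        raise ValueError("each validation group needs >=2 visits")

    severe_z = normalizer.transform(
        validation_matrix.subset_samples(severe_ids),
        [r for r in validation_records if r.sample_id in set(severe_ids)])

    ps = list(candidates.index)
    low = discovery_z.values.loc[ps, low_ids].to_numpy()
    high = discovery_z.values.loc[ps, high_ids].to_numpy()
    severe = severe_z.values.loc[ps].to_numpy()

    _, pvals = stats.f_oneway(low, high, severe, axis=1)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    n_candidates = len(ps)
    out = candidates.copy()
    lm, hm, sm = low.mean(axis=1), high.mean(axis=1), severe.mean(axis=1)
    inc = (candidates["direction"] == "increased").to_numpy()
    sw = np.where(inc, (lm < hm) & (hm < sm), (lm > hm) & (hm > sm))
    out["stepwise"] = sw
    out["anova_p"] = pvals
    out["validation_points"] = [
        validation_points(bool(s), max(float(p), np.finfo(float).tiny),
                          n_candidates, alpha, bonferroni_tier)
        for s, p in zip(sw, pvals)]
    out["cfe3"] = (out["internal_points"] + out["cfg_points"]
                   + out["validation_points"])
    return out
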