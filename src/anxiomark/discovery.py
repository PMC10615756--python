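"""Step 1 — within-subject discovery scoring of anxiety-tracking probesets.

Subjects contribute diametric pairs: consecutive visits whose anxiety labels
flip between LOW and HIGH. A probeset is scored by how concordantly it
changes across those pairs, by two methods: Differential Expression (DE,
the log-expression change exceeds a fold-change threshold) and
Absent/Present (AP, the detection call flips). The fraction of pairs
concordant with the probeset's majority direction maps onto an internal
score of up to 6 points: >=33% of pairs gives 2 points, >=50% gives 4, and
>=80% gives 6 (boundaries inclusive).

The fold-change threshold defaults to 1.2-fold (0.263 on the log2 scale).
It is exposed in configuration; upstream array pipelines differ in the
exact differential statistic they apply at this step, and the rule here is
the simplest one consistent with per-pair concordance counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import ExpressionMatrix, VisitRecord, StateLabel, label_state

#: 1.2-fold change on the log2 scale.
DEFAULT_DE_THRESHOLD = math.log2(1.2)

SCORE_TIERS = ((80.0, 6), (50.0, 4), (33.0, 2))


@dataclass(frozen=True)
class DiametricPair:
    """Two consecutive visits of one subject with opposite anxiety labels."""

    subject_id: str
    visit_low: str   # sample id of the LOW visit
    visit_high: str  # sample id of the HIGH visit
    order: Literal["low_to_high", "high_to_low"]


@dataclass(frozen=True)
class DiscoveryResult:
    probeset_id: str
    method: Literal["DE", "AP"]
    direction: Literal["increased", "decreased"]
    raw_score: int
    percent_of_max: float
    internal_points: int


def find_diametric_pairs(records: Sequence[VisitRecord],
                         all_pairs: bool = False) -> list[DiametricPair]:
    """Enumerate diametric visit pairs, consecutive by default.

    With ``all_pairs`` every LOW/HIGH visit combination of a subject counts,
    not just adjacent visits. A SEVERE visit counts as high-anxiety for
    pairing purposes; INTERMEDIATE visits never pair.
    """
    by_subject: dict[str, list[VisitRecord]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    pairs: list[DiametricPair] = []
    for sid in by_subject:
        visits = sorted(by_subject[sid], key=lambda r: r.visit_index)
        labels = [label_state(r) for r in visits]
        highish = {StateLabel.HIGH, StateLabel.SEVERE}
        if all_pairs:
            idx_pairs = [(i, j) for i in range(len(visits))
                         for j in range(i + 1, len(visits))]
        else:
            idx_pairs = [(i, i + 1) for i in range(len(visits) - 1)]
        for i, j in idx_pairs:
            a, b = labels[i], labels[j]
            if a is StateLabel.LOW and b in highish:
                pairs.append(DiametricPair(sid, visits[i].sample_id,
                                           visits[j].sample_id, "low_to_high"))
            elif a in highish and b is StateLabel.LOW:
                pairs.append(DiametricPair(sid, visits[j].sample_id,
                                           visits[i].sample_id, "high_to_low"))
    return pairs


def pair_concordance(pair: DiametricPair, matrix: ExpressionMatrix,
                     probeset_id: str, method: str,
                     de_fold_threshold: float = DEFAULT_DE_THRESHOLD) -> int:
    """Direction of change across one diametric pair: +1, -1, or 0.

    DE: +1 when expression rises from the LOW to the HIGH visit by at least
    the log fold-change threshold, -1 when it falls by at least that much.
    AP: +1 for an Absent-to-Present detection flip, -1 for the reverse.
    """
    if method == "DE":
        delta = (matrix.values.at[probeset_id, pair.visit_high]
                 - matrix.values.at[probeset_id, pair.visit_low])
        if delta >= de_fold_threshold:
            return 1
        if delta <= -de_fold_threshold:
            return -1
        return 0
    if method == "AP":
        if matrix.detection is None:
            raise ValueError("AP concordance requires detection calls")
        low = bool(matrix.detection.at[probeset_id, pair.visit_low])
        high = bool(matrix.detection.at[probeset_id, pair.visit_high])
        return int(high) - int(low)
    raise ValueError(f"unknown discovery method {method!r}")


def points_for_percent(percent: float) -> int:
    """Internal discovery points for a percent-of-maximum score."""
    for cut, pts in SCORE_TIERS:
        if percent >= cut:
            return pts
    return 0


def discovery_score(concordances: Sequence[int], probeset_id: str = "",
                    method: str = "DE") -> DiscoveryResult:
    """Fold per-pair concordances into a discovery score.

    The direction is the sign of the summed concordances (ties resolve to
    'increased'); the raw score counts pairs concordant with that direction;
    percent-of-max divides by the total number of diametric pairs, so a pair
    in which the probeset is silent counts against it.
    """
    n_pairs = len(concordances)
    if n_pairs == 0:
        raise ValueError("discovery_score needs at least one diametric pair")
    total = int(np.sum(concordances))
    direction = "increased" if total >= 0 else "decreased"
    wanted = 1 if direction == "increased" else -1
    raw = int(sum(1 for c in concordances if c == wanted))
    percent = 100.0 * raw / n_pairs
    return DiscoveryResult(probeset_id, method, direction, raw, percent,
                           points_for_percent(percent))


def score_discovery(matrix: ExpressionMatrix, records: Sequence[VisitRecord],
                    de_fold_threshold: float = DEFAULT_DE_THRESHOLD,
                    all_pairs: bool = False) -> pd.DataFrame:
    """Score every probeset by DE (and AP when calls exist) over all pairs.

    Returns a tidy frame, one row per probeset x method, with columns
    ``method, direction, raw_score, percent_of_max, internal_points``.
    """
    pairs = find_diametric_pairs(records, all_pairs=all_pairs)
    if not pairs:
        raise ValueError("cohort contains no diametric visit pairs")
    lows = [p.visit_low for p in pairs]
    highs = [p.visit_high for p in pairs]

    frames = []
    delta = matrix.values[highs].to_numpy() - matrix.values[lows].to_numpy()
    conc = np.where(delta >= de_fold_threshold, 1,
                    np.where(delta <= -de_fold_threshold, -1, 0))
    frames.append(_scores_from_concordance(conc, matrix.probeset_ids, "DE"))
    if matrix.detection is not None:
        flips = (matrix.detection[highs].to_numpy().astype(int)
                 - matrix.detection[lows].to_numpy().astype(int))
        frames.append(_scores_from_concordance(flips, matrix.probeset_ids, "AP"))
    return pd.concat(frames, ignore_index=True)


def _scores_from_concordance(conc: np.ndarray, probesets: Sequence[str],
                             method: str) -> pd.DataFrame:
    n_pairs = conc.shape[1]
    total = conc.sum(axis=1)
    increased = total >= 0
    wanted = np.where(increased, 1, -1)
    raw = (conc == wanted[:, None]).sum(axis=1)
    percent = 100.0 * raw / n_pairs
    points = np.zeros(len(probesets), dtype=int)
    for cut, pts in SCORE_TIERS:
        points = np.where((points == 0) & (percent >= cut), pts, points)
    return pd.DataFrame({
        "probeset": list(probesets), "method": method,
        "direction": np.where(increased, "increased", "decreased"),
        "raw_score": raw, "percent_of_max": percent, "internal_points": points,
    })


def best_discovery(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-probeset best method: the row with maximal internal points.

    A probeset may earn both a DE and an AP score; the scorecard keeps the
    maximum (DE wins ties so that AP, which needs detection calls, never
    displaces an equal DE score).
    """
    order = scores.assign(_m=(scores["method"] == "AP").astype(int))
    order = order.sort_values(["probeset", "internal_points", "percent_of_max", "_m"],
                              ascending=[True, False, False, True])
    best = order.drop_duplicates("probeset").drop(columns="_m")
    return best.set_index("probeset")
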