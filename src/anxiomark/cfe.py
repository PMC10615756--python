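"""Composite Convergent Functional Evidence (CFE) scoring and panels.

The final score for a biomarker adds, to the first three steps (discovery
up to 6, literature prioritization up to 12, validation up to 6 — CFE3, cap
24), the four prediction-testing categories at up to 3 points each, for a
total cap of 36: 24 points from the study's own cohorts and 12 from
literature evidence. Candidates with CFE3 >= 8 form the candidate panel;
the top of the CFE4 ranking forms compact biomarker panels (BioM-N) that
are aggregated into a single direction-aligned mean z-score predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .prediction import STEP4_TARGETS
from .validation import CFE3_GATE, cfe3_score

CFE4_MAX = 36.0


@dataclass
class BiomarkerScorecard:
    """Per-probeset accumulation of all four step scores."""

    probeset_id: str
    gene_symbol: str
    direction: str
    discovery_points: int
    cfg_points: float
    validation_points: int
    step4_points: Mapping[str, int] = field(default_factory=dict)

    @property
    def cfe3(self) -> float:
        return cfe3_score(self.discovery_points, self.cfg_points,
                          self.validation_points)

    @property
    def cfe4(self) -> float:
        return cfe4_score(self)


def cfe4_score(card: BiomarkerScorecard) -> float:
    """CFE3 plus the four per-category prediction points (maximum rule).

    Missing categories contribute 0; each category is bounded by 3.
    """
    total = card.cfe3
    for target in STEP4_TARGETS:
        pts = card.step4_points.get(target, 0)
        if pts not in (0, 1, 2, 3):
            raise ValueError(
                f"step-4 points for {target} must be 0..3, got {pts}")
        total += pts
    return float(total)


def build_scorecards(validated: pd.DataFrame,
                     step4: pd.DataFrame) -> list[BiomarkerScorecard]:
    """Assemble scorecards from the validation table and step-4 summary."""
    cards = []
    for ps, row in validated.iterrows():
        pts = ({t: int(step4.at[ps, t]) for t in STEP4_TARGETS}
               if ps in step4.index else {})
        cards.append(BiomarkerScorecard(
            probeset_id=str(ps), gene_symbol=str(row.get("gene_symbol", "")),
            direction=str(row["direction"]),
            discovery_points=int(row["internal_points"]),
            cfg_points=float(row["cfg_points"]),
            validation_points=int(row["validation_points"]),
            step4_points=pts))
    return cards


def scorecard_frame(cards: Sequence[BiomarkerScorecard]) -> pd.DataFrame:
    """Scorecards as a table mirroring the published panel layout."""
    rows = []
    for c in cards:
        row = dict(probeset=c.probeset_id, gene_symbol=c.gene_symbol,
                   direction=c.direction, discovery_points=c.discovery_points,
                   cfg_points=c.cfg_points, validation_points=c.validation_points)
        for t in STEP4_TARGETS:
            row[f"pts_{t}"] = c.step4_points.get(t, 0)
        row["cfe3"] = c.cfe3
        row["cfe4"] = c.cfe4
        rows.append(row)
    return pd.DataFrame(rows).set_index("probeset")


def select_top_panel(cards: Sequence[BiomarkerScorecard],
                     gate_cfe3: float = CFE3_GATE,
                     panel_size: int | None = None,
                     ) -> list[BiomarkerScorecard]:
    """Gate by CFE3 (inclusive) and optionally keep the top N by CFE4.

    Ties break by CFE3, then probeset id, so the panel is reproducible and
    invariant to input order.
    """
    if gate_cfe3 < 0:
        raise ValueError("gate must be nonnegative")
    kept = [c for c in cards if c.cfe3 >= gate_cfe3]
    kept.sort(key=lambda c: (-c.cfe4, -c.cfe3, c.probeset_id))
    if panel_size is not None:
        kept = kept[:panel_size]
    return kept


def panel_aggregate(panel: Sequence[BiomarkerScorecard],
                    expression: Mapping[str, float],
                    ) -> tuple[float, int]:
    """Direction-aligned mean z-score of the panel at one visit (BioM-N).

    ``expression`` maps probeset to z-scored level; decreased markers are
    negated before averaging. Returns (aggregate, number of missing panel
    members); all members missing is an error.
    """
    vals = []
    for card in panel:
        z = expression.get(card.probeset_id)
        if z is None or (isinstance(z, float) and np.isnan(z)):
            continue
        vals.append(-float(z) if card.direction == "decreased" else float(z))
    if not vals:
        raise ValueError("no panel member measured at this visit")
    return float(np.mean(vals)), len(panel) - len(vals)
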