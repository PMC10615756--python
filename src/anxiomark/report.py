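"""Digitized clinician report: risk percentiles and drug matching.

A patient's z-scored panel expression is digitized against reference group
averages: for an increased marker, 1 if at or above the high-anxiety group
mean, 0 if at or below the low-anxiety group mean, 0.5 in between (mirrored
for decreased markers). Markers whose reference means are not concordant
with their direction (high-group mean on the wrong side of the low-group
mean) are excluded from that report's denominator.

Digitized scores sum into percentile risk scores (state, first-year
hospitalization, all-future hospitalization; the two hospitalization
percentiles average into a chronic-risk score) and drive pharmacogenomic
matching: drugs known to modulate a patient's elevated biomarkers opposite
to their high-anxiety direction are ranked by a percentile match.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ThresholdEntry:
    """Reference group means for one probeset, on the z-scored scale."""

    probeset_id: str
    direction: str       # change in high anxiety: 'increased'/'decreased'
    high_group_mean: float
    low_group_mean: float

    @property
    def concordant(self) -> bool:
        if self.direction == "increased":
            return self.high_group_mean > self.low_group_mean
        return self.high_group_mean < self.low_group_mean


def compute_thresholds(z_values: pd.DataFrame, positive_samples: Sequence[str],
                       negative_samples: Sequence[str],
                       directions: Mapping[str, str]) -> dict[str, ThresholdEntry]:
    """Per-probeset reference means from positive/negative reference groups."""
    if not positive_samples or not negative_samples:
        raise ValueError("both reference groups must be non-empty")
    high = z_values[list(positive_samples)].mean(axis=1)
    low = z_values[list(negative_samples)].mean(axis=1)
    return {ps: ThresholdEntry(ps, directions[ps], float(high[ps]), float(low[ps]))
            for ps in directions if ps in z_values.index}


def digitize_biomarker(z_value: float, entry: ThresholdEntry) -> float:
    """Digitize one marker level to 0, 0.5, or 1 against its thresholds."""
    if not entry.concordant:
        raise ValueError(
            f"thresholds for {entry.probeset_id} are not concordant; "
            "marker must be excluded from the panel denominator")
    if entry.direction == "increased":
        if z_value >= entry.high_group_mean:
            return 1.0
        if z_value <= entry.low_group_mean:
            return 0.0
        return 0.5
    if z_value <= entry.high_group_mean:
        return 1.0
    if z_value >= entry.low_group_mean:
        return 0.0
    return 0.5


def digitize_panel(z_expression: Mapping[str, float],
                   thresholds: Mapping[str, ThresholdEntry],
                   ) -> tuple[dict[str, float], list[str]]:
    """Digitize every concordant panel member; return scores and exclusions."""
    scores: dict[str, float] = {}
    excluded: list[str] = []
    for ps, entry in thresholds.items():
        if not entry.concordant:
            excluded.append(ps)
            continue
        z = z_expression.get(ps)
        if z is None or (isinstance(z, float) and np.isnan(z)):
            excluded.append(ps)
            continue
        scores[ps] = digitize_biomarker(float(z), entry)
    return scores, excluded


def risk_percentile(scores: Mapping[str, float] | Sequence[float]) -> float:
    """Polygenic percentile: digitized scores summed and normalized by the
    number of included panel members, on a 0-100 scale."""
    vals = list(scores.values()) if isinstance(scores, Mapping) else list(scores)
    if not vals:
        raise ValueError("risk percentile needs at least one included marker")
    return 100.0 * float(np.sum(vals)) / len(vals)


def drug_match_percentile(scores: Mapping[str, float], drug_table: pd.DataFrame,
                          genes: Mapping[str, str],
                          directions: Mapping[str, str],
                          ) -> dict[str, float | None]:
    """Percentile match of each drug to the patient's digitized profile.

    Only (drug, gene) rows modulating opposite to the marker's high-anxiety
    direction count. Each matched marker contributes its digitized score;
    the sum is normalized by the number of the patient's markers scoring at
    least 0.5. With no such markers every drug's match is undefined (None).
    """
    denominator = sum(1 for v in scores.values() if v >= 0.5)
    opposite = {"increased": "decreases", "decreased": "increases"}
    matches: dict[str, float] = {d: 0.0 for d in drug_table["drug"].unique()}
    for _, row in drug_table.iterrows():
        for ps, score in scores.items():
            if genes.get(ps) == row["gene"] and \
                    row["modulation"] == opposite[directions[ps]]:
                matches[row["drug"]] += score
    if denominator == 0:
        return {d: None for d in matches}
    return {d: 100.0 * s / denominator for d, s in matches.items()}


def drug_coverage(panel_genes: Mapping[str, str],
                  directions_by_gene: Mapping[str, str],
                  drug_table: pd.DataFrame) -> dict[str, float]:
    """Panel-level drug coverage: percent of unique panel genes a drug
    modulates opposite to their high-anxiety direction.

    ``panel_genes`` maps probeset to gene symbol; duplicated probesets of
    one gene collapse to a single denominator entry.
    """
    genes = sorted(set(panel_genes.values()))
    if not genes:
        raise ValueError("empty panel")
    opposite = {"increased": "decreases", "decreased": "increases"}
    coverage: dict[str, float] = {}
    for drug, grp in drug_table.groupby("drug"):
        hit = 0
        for gene in genes:
            want = opposite[directions_by_gene[gene]]
            if ((grp["gene"] == gene) & (grp["modulation"] == want)).any():
                hit += 1
        coverage[str(drug)] = 100.0 * hit / len(genes)
    return coverage


def clinician_report(subject_id: str, z_expression: Mapping[str, float],
                     thresholds_state: Mapping[str, ThresholdEntry],
                     thresholds_first_year: Mapping[str, ThresholdEntry],
                     thresholds_all_future: Mapping[str, ThresholdEntry],
                     drug_table: pd.DataFrame, genes: Mapping[str, str],
                     directions: Mapping[str, str],
                     nutraceuticals: Sequence[str] = (),
                     ) -> dict:
    """Structured report for one subject-visit (JSON-serializable).

    Emits per-marker digitized scores against the three reference pairs,
    the three percentile risk scores, a combined chronic-risk score (mean
    of the two hospitalization percentiles), and ranked medication /
    nutraceutical match lists from the state profile.
    """
    sections = {}
    percentiles = {}
    state_scores: dict[str, float] = {}
    for name, thresholds in (("state", thresholds_state),
                             ("first_year_hosp", thresholds_first_year),
                             ("all_future_hosp", thresholds_all_future)):
        scores, excluded = digitize_panel(z_expression, thresholds)
        sections[name] = {"scores": scores, "excluded": sorted(excluded),
                          "n_included": len(scores)}
        percentiles[name] = risk_percentile(scores) if scores else None
        if name == "state":
            state_scores = scores
    hosp = [percentiles["first_year_hosp"], percentiles["all_future_hosp"]]
    chronic = (float(np.mean([v for v in hosp if v is not None]))
               if any(v is not None for v in hosp) else None)

    match = drug_match_percentile(state_scores, drug_table, genes, directions)
    ranked = sorted(((d, m) for d, m in match.items() if m is not None),
                    key=lambda kv: (-kv[1], kv[0]))
    nutra = set(nutraceuticals)
    report = {
        "subject_id": subject_id,
        "markers": sections,
        "risk_percentiles": {**percentiles, "chronic_combined": chronic},
        "medication_matches": [
            {"drug": d, "match": m} for d, m in ranked if d not in nutra],
        "nutraceutical_matches": [
            {"drug": d, "match": m} for d, m in ranked if d in nutra],
    }
    return report


def render_report_text(report: dict) -> str:
    """Human-readable rendering of a clinician report."""
    lines = [f"Anxiety biomarker panel report — subject {report['subject_id']}", ""]
    rp = report["risk_percentiles"]
    for key, label in (("state", "Current anxiety state"),
                       ("first_year_hosp", "First-year hospitalization risk"),
                       ("all_future_hosp", "Future hospitalization risk"),
                       ("chronic_combined", "Combined chronic risk")):
        val = rp.get(key)
        lines.append(f"{label:35s} {'n/a' if val is None else f'{val:5.1f} %'}")
    for section, title in (("medication_matches", "Top medication matches"),
                           ("nutraceutical_matches", "Top nutraceutical matches")):
        entries = report[section]
        if entries:
            lines.append("")
            lines.append(title + ":")
            for entry in entries[:10]:
                lines.append(f"  {entry['drug']:30s} {entry['match']:5.1f} %")
    excluded = report["markers"]["state"]["excluded"]
    if excluded:
        lines.append("")
        lines.append(f"Markers excluded (non-concordant or unmeasured): "
                     f"{', '.join(excluded)}")
    return "\n".join(lines) + "\n"


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
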