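"""Step 2 — convergent-evidence prioritization of discovery candidates.

Gene-level literature evidence (genetic, brain expression, peripheral
expression; human and animal) is aggregated into a prioritization score
capped at 12 points: six species-by-kind categories, each capped at 2
points, so a gene with evidence of every kind in both species saturates.
Protein-level evidence folds into the expression category of its tissue.
The prioritization score is added to the internal discovery points (cap 6)
and candidates with a combined score of at least 6 (of a possible 18) are
carried into validation.

The per-category weighting is a documented, configurable default; only the
12-point cap is externally fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

SPECIES = ("human", "animal")
EVIDENCE_KINDS = ("genetic", "expression_brain", "expression_peripheral", "protein")

#: (species, kind) -> cap. Six categories x 2 points = the 12-point maximum.
DEFAULT_CATEGORY_CAPS: dict[tuple[str, str], float] = {
    (sp, kind): 2.0
    for sp in SPECIES
    for kind in ("genetic", "expression_brain", "expression_peripheral")
}

CFG_MAX = 12.0
COMBINED_GATE = 6.0


@dataclass(frozen=True)
class CandidateScore:
    probeset_id: str
    gene_symbol: str
    discovery_points: int
    cfg_points: float

    @property
    def combined(self) -> float:
        return self.discovery_points + self.cfg_points


def _fold_protein(species: str, kind: str, tissue: str | None) -> tuple[str, str]:
    if kind == "protein":
        target = "expression_brain" if tissue == "brain" else "expression_peripheral"
        return species, target
    return species, kind


def cfg_score(gene_symbol: str, table: pd.DataFrame,
              category_caps: Mapping[tuple[str, str], float] | None = None,
              total_cap: float = CFG_MAX) -> float:
    """Convergent-evidence points for one gene, capped per category and overall.

    ``table`` has columns ``gene_symbol, species, evidence_kind, weight`` and
    optionally ``tissue`` (used to fold protein evidence into an expression
    category). Unknown species or evidence kinds are hard errors.
    """
    caps = dict(category_caps) if category_caps is not None else DEFAULT_CATEGORY_CAPS
    rows = table[table["gene_symbol"] == gene_symbol]
    sums: dict[tuple[str, str], float] = {}
    for _, row in rows.iterrows():
        species, kind = row["species"], row["evidence_kind"]
        if species not in SPECIES:
            raise ValueError(f"unknown species {species!r} for {gene_symbol}")
        if kind not in EVIDENCE_KINDS:
            raise ValueError(f"unknown evidence kind {kind!r} for {gene_symbol}")
        cat = _fold_protein(species, kind, row.get("tissue"))
        if cat not in caps:
            raise ValueError(f"no cap configured for category {cat}")
        weight = float(row["weight"])
        if weight <= 0:
            raise ValueError(f"evidence weight must be positive ({gene_symbol})")
        sums[cat] = sums.get(cat, 0.0) + weight
    total = sum(min(v, caps[cat]) for cat, v in sums.items())
    return min(total, total_cap)


def score_candidates(discovery: pd.DataFrame, evidence: pd.DataFrame,
                     gene_map: Mapping[str, str],
                     category_caps: Mapping[tuple[str, str], float] | None = None,
                     ) -> pd.DataFrame:
    """Attach gene symbols and convergent-evidence points to discovery scores.

    ``discovery`` is the per-probeset best-method frame (indexed by
    probeset). Probesets without a gene symbol keep 0 evidence points but
    stay eligible through their discovery points.
    """
    genes = pd.Series({ps: gene_map.get(ps) for ps in discovery.index},
                      name="gene_symbol")
    unique_genes = sorted({g for g in genes if g})
    per_gene = {g: cfg_score(g, evidence, category_caps) for g in unique_genes}
    out = discovery.copy()
    out["gene_symbol"] = genes
    out["cfg_points"] = [per_gene.get(g, 0.0) if g else 0.0 for g in genes]
    out["combined"] = out["internal_points"] + out["cfg_points"]
    return out


def select_candidates(scored: pd.DataFrame,
                      gate: float = COMBINED_GATE) -> pd.DataFrame:
    """Keep candidates whose combined score reaches the gate (inclusive).

    Sorted by descending combined score, then probeset id, so the output is
    invariant to input order.
    """
    if gate < 0:
        raise ValueError("gate must be nonnegative")
    kept = scored[scored["combined"] >= gate].copy()
    kept["_ps"] = kept.index
    kept = kept.sort_values(["combined", "_ps"], ascending=[False, True])
    return kept.drop(columns="_ps")
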