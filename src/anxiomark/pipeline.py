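"""End-to-end orchestration of the four-step biomarker pipeline.

Stages mirror the study flow — simulate (or load) cohorts, discover,
prioritize, validate, test, score, report — and each stage persists its
output under the run directory so any stage can be re-run from
intermediates. A manifest records the full configuration, seed, and stage
record counts; identical configuration and inputs produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .cfe import build_scorecards, scorecard_frame, select_top_panel
from .cfg import COMBINED_GATE, score_candidates, select_candidates
from .cohort import (ExpressionMatrix, StratumNormalizer, read_cohort,
                     write_cohort, zscore_by_stratum, label_state, StateLabel)
from .discovery import DEFAULT_DE_THRESHOLD, best_discovery, score_discovery
from .prediction import step4_summary, test_candidates
from .report import (clinician_report, compute_thresholds, render_report_text,
                     report_to_json)
from .simulate import (SimulationConfig, cohort_subset, simulate_cohort,
                       simulate_evidence_table)
from .validation import CFE3_GATE, validate_candidates

log = logging.getLogger(__name__)

COHORTS = ("discovery", "validation", "test")

#: Nutraceuticals / non-pharmacological entries recognized in drug tables.
NUTRACEUTICALS = ("Omega-3 fatty acids", "S-adenosyl methionine (SAM)",
                  "Gamma frequency")


@dataclass
class PipelineConfig:
    """All thresholds and inputs of a pipeline run.

    Defaults are exactly the published cutoffs: SAS-4 <=40 / >=60, STAI
    >=55, discovery tiers 33/50/80 -> 2/4/6, combined gate 6, CFE3 gate 8,
    alpha 0.05 with Bonferroni over the tested panel.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    de_fold_threshold: float = DEFAULT_DE_THRESHOLD
    combined_gate: float = COMBINED_GATE
    cfe3_gate: float = CFE3_GATE
    alpha: float = 0.05
    evidence_sensitivity: float = 0.8
    evidence_fpr: float = 0.05
    panel_size: int | None = 19
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulation, Mapping):
            self.simulation = SimulationConfig(**self.simulation)
        self.simulation.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["visits_per_subject"] = {
            str(k): v for k, v in d["simulation"]["visits_per_subject"].items()}
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        if "visits_per_subject" in sim:
            sim["visits_per_subject"] = {
                int(k): float(v) for k, v in sim["visits_per_subject"].items()}
        return cls(simulation=SimulationConfig(**sim), **raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _paths(outdir: str | Path) -> dict[str, Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    return {
        **{f"{c}_{kind}": out / f"{c}_{kind}.csv"
           for c in COHORTS for kind in ("expression", "metadata", "detection")},
        "truth": out / "truth.csv",
        "evidence": out / "evidence.csv",
        "discovery_scores": out / "discovery_scores.csv",
        "candidates": out / "candidates.csv",
        "validation": out / "validation_results.csv",
        "predictions": out / "prediction_results.csv",
        "scorecards": out / "scorecards.csv",
        "panel": out / "panel.json",
        "manifest": out / "manifest.json",
        "config": out / "config.yaml",
        "out": out,
    }


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: PipelineConfig, outdir: str | Path) -> None:
    """Generate the three cohorts, evidence table, and ground truth."""
    paths = _paths(outdir)
    matrix, records, truth = simulate_cohort(config.simulation)
    for cohort in COHORTS:
        sub, recs = cohort_subset(matrix, records, truth, cohort)
        write_cohort(sub, recs, paths[f"{cohort}_expression"],
                     paths[f"{cohort}_metadata"], paths[f"{cohort}_detection"])
    rows = []
    for ps in truth.probeset_ids:
        role = ("state" if ps in truth.state_marker_ids
                else "trait" if ps in truth.trait_marker_ids else "null")
        rows.append({"probeset": ps, "gene_symbol": truth.gene_map[ps],
                     "role": role, "direction": truth.directions[ps],
                     "effect": (truth.state_effect if role == "state"
                                else truth.trait_effect if role == "trait"
                                else 0.0)})
    pd.DataFrame(rows).to_csv(paths["truth"], index=False)
    evidence = simulate_evidence_table(
        truth, config.evidence_sensitivity, config.evidence_fpr,
        seed=config.seed + 1)
    evidence.to_csv(paths["evidence"], index=False)
    log.info("simulated %d probesets, %d visits", len(truth.probeset_ids),
             len(records))


def _load_cohort(paths: Mapping[str, Path], cohort: str):
    det = paths[f"{cohort}_detection"]
    return read_cohort(paths[f"{cohort}_expression"], paths[f"{cohort}_metadata"],
                       det if det.exists() else None)


def stage_discover(config: PipelineConfig, outdir: str | Path) -> None:
    """Step 1: score probesets over diametric pairs of the discovery cohort."""
    paths = _paths(outdir)
    matrix, records = _load_cohort(paths, "discovery")
    scores = score_discovery(matrix, records,
                             de_fold_threshold=config.de_fold_threshold)
    scores.to_csv(paths["discovery_scores"], index=False)
    n_pass = (best_discovery(scores)["internal_points"] >= 2).sum()
    log.info("discovery: %d/%d probesets at >=2 points", n_pass,
             scores["probeset"].nunique())


def stage_prioritize(config: PipelineConfig, outdir: str | Path) -> None:
    """Step 2: evidence scoring and the combined >=6 gate."""
    paths = _paths(outdir)
    scores = pd.read_csv(paths["discovery_scores"])
    evidence = pd.read_csv(paths["evidence"])
    gene_map = dict(pd.read_csv(paths["truth"])[
        ["probeset", "gene_symbol"]].itertuples(index=False))
    best = best_discovery(scores)
    scored = score_candidates(best, evidence, gene_map)
    kept = select_candidates(scored, gate=config.combined_gate)
    kept.to_csv(paths["candidates"], index_label="probeset")
    log.info("prioritization: %d candidates at combined >= %s", len(kept),
             config.combined_gate)


def stage_validate(config: PipelineConfig, outdir: str | Path) -> None:
    """Step 3: stepwise/ANOVA validation in the severe-anxiety cohort."""
    paths = _paths(outdir)
    candidates = pd.read_csv(paths["candidates"], index_col="probeset")
    disc_matrix, disc_records = _load_cohort(paths, "discovery")
    val_matrix, val_records = _load_cohort(paths, "validation")
    normalizer = StratumNormalizer().fit(disc_matrix, disc_records)
    disc_z = normalizer.transform(disc_matrix, disc_records)
    validated = validate_candidates(candidates, disc_z, disc_records,
                                    val_matrix, val_records, normalizer,
                                    alpha=config.alpha)
    validated.to_csv(paths["validation"], index_label="probeset")
    log.info("validation: %d stepwise, %d at CFE3 >= %s",
             int(validated["stepwise"].sum()),
             int((validated["cfe3"] >= config.cfe3_gate).sum()), config.cfe3_gate)


def stage_test(config: PipelineConfig, outdir: str | Path) -> None:
    """Step 4: stratified state/trait predictive testing of top candidates."""
    paths = _paths(outdir)
    validated = pd.read_csv(paths["validation"], index_col="probeset")
    top = validated[validated["cfe3"] >= config.cfe3_gate]
    if top.empty:
        raise RuntimeError("no candidates reached the CFE3 gate")
    matrix, records = _load_cohort(paths, "test")
    test_z = zscore_by_stratum(matrix, records)
    results = test_candidates(top, test_z, records, alpha=config.alpha,
                              n_biomarkers=len(top))
    results.to_csv(paths["predictions"], index=False)
    log.info("testing: %d candidates x %d result rows", len(top), len(results))


def stage_score(config: PipelineConfig, outdir: str | Path) -> None:
    """Compose CFE scorecards and the top biomarker panel."""
    paths = _paths(outdir)
    validated = pd.read_csv(paths["validation"], index_col="probeset")
    results = pd.read_csv(paths["predictions"])
    top = validated[validated["cfe3"] >= config.cfe3_gate]
    step4 = step4_summary(results, alpha=config.alpha)
    cards = build_scorecards(top, step4)
    frame = scorecard_frame(cards).sort_values(
        ["cfe4", "cfe3"], ascending=False, kind="mergesort")
    frame.to_csv(paths["scorecards"], index_label="probeset")
    panel = select_top_panel(cards, gate_cfe3=config.cfe3_gate,
                             panel_size=config.panel_size)
    with open(paths["panel"], "w") as fh:
        json.dump({"panel": [{"probeset": c.probeset_id, "gene": c.gene_symbol,
                              "direction": c.direction, "cfe4": c.cfe4}
                             for c in panel]}, fh, indent=2)
    log.info("scored %d cards; panel of %d", len(cards), len(panel))


def stage_report(config: PipelineConfig, outdir: str | Path,
                 subject_id: str | None = None) -> dict:
    """Digitized clinician report for one test-cohort subject (most recent
    visit); defaults to the first test subject."""
    paths = _paths(outdir)
    with open(paths["panel"]) as fh:
        panel = json.load(fh)["panel"]
    directions = {e["probeset"]: e["direction"] for e in panel}
    genes = {e["probeset"]: e["gene"] for e in panel}
    matrix, records = _load_cohort(paths, "test")
    test_z = zscore_by_stratum(matrix, records)

    def group(pred):
        return [r.sample_id for r in records if pred(r)]

    pairs = {
        "state": (group(lambda r: r.sas4 >= 60.0), group(lambda r: r.sas4 <= 40.0)),
        "first": (group(lambda r: r.followup_first_year_hosp is True),
                  group(lambda r: r.followup_first_year_hosp is False)),
        "future": (group(lambda r: r.followup_any_future_hosp is True),
                   group(lambda r: r.followup_any_future_hosp is False)),
    }
    thresholds = {k: compute_thresholds(test_z.values, pos, neg, directions)
                  for k, (pos, neg) in pairs.items()}

    if subject_id is None:
        subject_id = records[0].subject_id
    visits = sorted((r for r in records if r.subject_id == subject_id),
                    key=lambda r: r.visit_index)
    if not visits:
        raise ValueError(f"unknown subject {subject_id!r}")
    sample = visits[-1].sample_id
    z_expr = {ps: float(test_z.values.at[ps, sample]) for ps in directions
              if ps in test_z.values.index}

    drug_rows = []
    # simulated drug table: every planted gene has one opposite-direction drug
    truth = pd.read_csv(paths["truth"])
    for _, row in truth[truth["role"] != "null"].iterrows():
        mod = "decreases" if row["direction"] == "increased" else "increases"
        drug_rows.append({"drug": f"drug_{row['gene_symbol']}",
                          "gene": row["gene_symbol"], "modulation": mod})
    drug_table = pd.DataFrame(drug_rows, columns=["drug", "gene", "modulation"])

    report = clinician_report(subject_id, z_expr, thresholds["state"],
                              thresholds["first"], thresholds["future"],
                              drug_table, genes, directions,
                              nutraceuticals=NUTRACEUTICALS)
    with open(paths["out"] / f"report_{subject_id}.json", "w") as fh:
        fh.write(report_to_json(report))
    with open(paths["out"] / f"report_{subject_id}.txt", "w") as fh:
        fh.write(render_report_text(report))
    return report


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage in order and write the run manifest."""
    paths = _paths(outdir)
    config.to_yaml(paths["config"])
    stage_simulate(config, outdir)
    stage_discover(config, outdir)
    stage_prioritize(config, outdir)
    stage_validate(config, outdir)
    stage_test(config, outdir)
    stage_score(config, outdir)
    stage_report(config, outdir)

    config_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()
    counts = {name: sum(1 for _ in open(paths[name])) - 1
              for name in ("candidates", "validation", "predictions", "scorecards")}
    manifest = {"version": __version__, "seed": config.seed,
                "config_sha256": config_hash, "record_counts": counts}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths["out"]
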