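"""Published reference panel of top blood biomarkers for anxiety.

The 19-probeset / 18-gene panel that emerged from the four-step framework
(within-subject discovery, convergent-evidence prioritization, stepwise
validation in clinically severe anxiety, and stratified state/trait
prediction testing), together with the published per-step component scores
and the strata in which each probeset predicted significantly. These
component cells are the inputs to the composite Convergent Functional
Evidence (CFE) arithmetic and to the drug-coverage calculations; they are
reference *data*, not values the pipeline computes.

Step-4 strata use the labels ``ALL`` (all test subjects), ``M``/``F``
(gender), and ``<gender>-<dx>`` (gender by primary diagnosis, with
``PSYCHOSIS`` pooling schizophrenia and schizoaffective).

Drugs listed per probeset modulate that biomarker's expression in the
direction *opposite* to its change in high anxiety.
"""

from __future__ import annotations

import pandas as pd

#: The four Step-4 prediction categories, in panel-table order.
STEP4_TARGETS = ("state_sas4", "state_stai", "hosp_first_year", "hosp_all_future")

#: Reference panel rows. ``direction`` is the change in high anxiety.
TOP19_PANEL: list[dict] = [
    dict(
        probeset="205278_at", gene="GAD1", direction="increased",
        discovery_method="DE", discovery_percent=62.3, discovery_points=4,
        cfg_points=11, validation_p=6.79e-01, validation_stepwise=False,
        validation_points=0,
        step4_strata={
            "state_sas4": [],
            "state_stai": ["ALL", "F", "F-PSYCHOSIS", "F-SZ"],
            "hosp_first_year": ["M-PSYCHOSIS", "M-SZA"],
            "hosp_all_future": ["ALL", "M", "M-BP", "M-PSYCHOSIS", "M-SZA"],
        },
        drugs=["Carbamazepine", "Lithium", "Omega-3 fatty acids", "Valproate"],
        cfe4_published=22,
    ),
    dict(
        probeset="215311_at", gene="NTRK3", direction="increased",
        discovery_method="DE", discovery_percent=53.2, discovery_points=4,
        cfg_points=4, validation_p=3.26e-01, validation_stepwise=True,
        validation_points=2,
        step4_strata={
            "state_sas4": ["M", "M-PSYCHOSIS", "M-SZA"],
            "state_stai": ["ALL", "F", "F-BP", "M-MDD"],
            "hosp_first_year": ["F-PSYCHOSIS", "F-SZA"],
            "hosp_all_future": ["ALL", "F"],
        },
        drugs=["Clozapine"],
        cfe4_published=19,
    ),
    dict(
        probeset="209869_at", gene="ADRA2A", direction="increased",
        discovery_method="AP", discovery_percent=50.0, discovery_points=4,
        cfg_points=4, validation_p=9.07e-01, validation_stepwise=False,
        validation_points=0,
        step4_strata={
            "state_sas4": ["M-MDD"],
            "state_stai": ["F", "F-SZ"],
            "hosp_first_year": ["ALL", "M", "M-PSYCHOSIS", "M-PTSD", "M-SZ"],
            "hosp_all_future": ["ALL", "M", "M-PSYCHOSIS", "M-PTSD", "M-SZ"],
        },
        drugs=["Carbamazepine", "Clozapine", "Norfluoxetine", "Valproate"],
        cfe4_published=17,
    ),
    dict(
        probeset="219764_at", gene="FZD10", direction="increased",
        discovery_method="DE", discovery_percent=53.2, discovery_points=4,
        cfg_points=2, validation_p=3.57e-01, validation_stepwise=True,
        validation_points=2,
        step4_strata={
            "state_sas4": [],
            "state_stai": ["ALL", "F", "F-BP", "F-SZA", "F-SZ"],
            "hosp_first_year": ["ALL", "M", "M-PSYCHOSIS", "M-SZ"],
            "hosp_all_future": ["ALL", "M", "M-PSYCHOSIS", "M-SZ"],
        },
        drugs=["Aripiprazole", "Fluoxetine", "Gamma frequency"],
        cfe4_published=17,
    ),
    dict(
        probeset="210600_s_at", gene="GRK4", direction="increased",
        discovery_method="DE", discovery_percent=81.8, discovery_points=6,
        cfg_points=0, validation_p=3.40e-01, validation_stepwise=True,
        validation_points=2,
        step4_strata={
            "state_sas4": ["M-MDD"],
            "state_stai": ["F", "F-BP", "M-MDD"],
            "hosp_first_year": ["ALL", "M"],
            "hosp_all_future": ["ALL", "M", "F-MDD", "M-PSYCHOSIS"],
        },
        drugs=["Clozapine", "Gamma frequency"],
        cfe4_published=17,
    ),
    dict(
        probeset="204311_at", gene="ATP1B2", direction="increased",
        discovery_method="DE", discovery_percent=39.0, discovery_points=2,
        cfg_points=4, validation_p=1.65e-01, validation_stepwise=True,
        validation_points=2,
        step4_strata={
            "state_sas4": ["M-MDD"],
            "state_stai": ["F", "F-BP", "F-PSYCHOSIS"],
            "hosp_first_year": ["M", "M-PSYCHOSIS", "M-PTSD", "M-SZ"],
            "hosp_all_future": ["ALL", "F", "M", "F-MDD", "M-BP",
                               "M-PSYCHOSIS", "M-SZ", "M-SZA"],
        },
        drugs=["Acetyldigitoxin", "Clozapine", "Deslanoside", "Digitoxin",
               "Digoxin", "Haloperidol", "Lithium", "Valproate"],
        cfe4_published=16,
    ),
    dict(
        probeset="242913_at", gene="CLIC6", direction="increased",
        discovery_method="AP", discovery_percent=84.2, discovery_points=6,
        cfg_points=2, validation_p=5.06e-01, validation_stepwise=False,
        validation_points=0,
        step4_strata={
            "state_sas4": [],
            "state_stai": ["F", "F-BP", "F-PSYCHOSIS", "F-SZ", "F-SZA"],
            "hosp_first_year": ["ALL", "M-PSYCHOSIS", "M-SZ"],
            "hosp_all_future": ["ALL", "F", "M", "M-SZ"],
        },
        drugs=["Clozapine", "Omega-3 fatty acids", "Gamma frequency"],
        cfe4_published=16,
    ),
    dict(
        probeset="1559360_at", gene="EFNA5", direction="increased",
        discovery_method="DE", discovery_percent=80.5, discovery_points=6,
        cfg_points=2, validation_p=2.02e-04, validation_stepwise=True,
        validation_points=4,
        step4_strata={
            "state_sas4": [],
            "state_stai": ["F", "M-SZ"],
            "hosp_first_year": ["ALL", "M", "F-SZA", "M-SZA"],
            "hosp_all_future": ["M-BP"],
        },
        drugs=["Omega-3 fatty acids", "Gamma frequency"],
        cfe4_published=18,
    ),
    dict(
        probeset="213170_at", gene="GPX7", direction="decreased",
        discovery_method="DE", discovery_percent=64.3, discovery_points=4,
        cfg_points=2, validation_p=4.64e-01, validation_stepwise=True,
        validation_points=2,
        step4_strata={
            "state_sas4": ["ALL"],
            "state_stai": ["F-BP", "F-SZA", "M-MDD"],
            "hosp_first_year": ["M-PSYCHOSIS", "M-SZ"],
            "hosp_all_future": ["ALL", "M", "M-PSYCHOSIS", "M-SZ"],
        },
        drugs=["Mianserin", "S-adenosyl methionine (SAM)"],
        cfe4_published=16,
    ),
    dict(
        probeset="215025_at", gene="NTRK3", direction="increased",
        discovery_method="DE", discovery_percent=35.1, discovery_points=2,
        cfg_points=4, validation_p=6.58e-01, validation_stepwise=True,
        validation_points=2,
        step4_strata={
            "state_sas4": ["M-BP"],
            "state_stai": ["ALL", "F", "M", "F-BP", "F-PSYCHOSIS", "F-SZ", "M-BP"],
            "hosp_first_year": ["M-PSYCHOSIS", "M-SZ"],
            "hosp_all_future": ["ALL", "M", "M-BP", "M-PSYCHOSIS", "M-SZ"],
        },
        drugs=["Clozapine"],
        cfe4_published=16,
    ),
    dict(
        probeset="217214_s_at", gene="SLC6A2", direction="increased",
        discovery_method="DE", discovery_percent=40.3, discovery_points=2,
        cfg_points=4, validation_p=3.40e-01, validation_stepwise=True,
        validation_points=2,
        step4_strata={
            "state_sas4": ["F-PSYCHOSIS", "F-SZA"],
            "state_stai": ["ALL", "F", "F-MDD", "F-PSYCHOSIS", "F-SZ", "M-SZ"],
            "hosp_first_year": ["M-PSYCHOSIS", "M-SZA", "M-SZ"],
            "hosp_all_future": ["ALL", "M", "M-BP", "M-PSYCHOSIS"],
        },
        drugs=["Fluoxetine", "Norfluoxetine"],
        cfe4_published=16,
    ),
    dict(
        probeset="242009_at", gene="SLC6A4", direction="increased",
        discovery_method="DE", discovery_percent=35.1, discovery_points=2,
        cfg_points=10, validation_p=8.51e-01, validation_stepwise=False,
        validation_points=0,
        step4_strata={
            "state_sas4": [],
            "state_stai": [],
            "hosp_first_year": ["F-PSYCHOSIS", "F-SZA", "M-PTSD", "M-SZ"],
            "hosp_all_future": ["ALL", "M", "M-PTSD"],
        },
        drugs=["Agomelatine", "Benzodiazepines", "Citalopram", "Clozapine",
               "Omega-3 fatty acids", "Oxycodone", "Sertraline", "Vortioxetine"],
        cfe4_published=16,
    ),
    dict(
        probeset="223113_at", gene="TMEM138", direction="decreased",
        discovery_method="DE", discovery_percent=63.0, discovery_points=4,
        cfg_points=4, validation_p=8.63e-01, validation_stepwise=False,
        validation_points=0,
        step4_strata={
            "state_sas4": [],
            "state_stai": ["M", "F-BP"],
            "hosp_first_year": ["ALL", "M-PTSD"],
            "hosp_all_future": ["ALL", "M", "M-PSYCHOSIS", "M-PTSD", "M-SZA"],
        },
        drugs=["Antidepressants"],
        cfe4_published=16,
    ),
    dict(
        probeset="229307_at", gene="ANKRD28", direction="increased",
        discovery_method="DE", discovery_percent=80.5, discovery_points=6,
        cfg_points=0, validation_p=6.20e-01, validation_stepwise=True,
        validation_points=2,
        step4_strata={
            "state_sas4": [],
            "state_stai": ["ALL", "M", "M-MDD", "M-PSYCHOSIS", "M-SZ"],
            "hosp_first_year": ["F-PSYCHOSIS", "F-SZA"],
            "hosp_all_future": ["ALL", "M", "F-MDD", "M-PSYCHOSIS", "M-SZA"],
        },
        drugs=[],
        cfe4_published=15,
    ),
    dict(
        probeset="210381_s_at", gene="CCKBR", direction="increased",
        discovery_method="DE", discovery_percent=48.0, discovery_points=2,
        cfg_points=4, validation_p=4.37e-01, validation_stepwise=True,
        validation_points=2,
        step4_strata={
            "state_sas4": [],
            "state_stai": ["F-BP", "M-BP"],
            "hosp_first_year": ["ALL", "M", "F-PSYCHOSIS", "F-SZA",
                               "M-PTSD", "M-SZ"],
            "hosp_all_future": ["ALL", "M", "M-PSYCHOSIS"],
        },
        drugs=["Clozapine"],
        cfe4_published=15,
    ),
    dict(
        probeset="229106_at", gene="DYNLL2", direction="decreased",
        discovery_method="DE", discovery_percent=39.3, discovery_points=2,
        cfg_points=4, validation_p=1.96e-01, validation_stepwise=True,
        validation_points=2,
        step4_strata={
            "state_sas4": ["M", "M-BP"],
            "state_stai": ["F-SZA"],
            "hosp_first_year": ["ALL"],
            "hosp_all_future": ["M-SZA"],
        },
        drugs=["Benzodiazepines", "Valproate"],
        cfe4_published=15,
    ),
    dict(
        probeset="240253_at", gene="Hs.550187", direction="increased",
        discovery_method="DE", discovery_percent=88.3, discovery_points=6,
        cfg_points=0, validation_p=2.74e-01, validation_stepwise=True,
        validation_points=2,
        step4_strata={
            "state_sas4": [],
            "state_stai": ["F", "F-BP"],
            "hosp_first_year": ["F", "F-SZA", "M-PSYCHOSIS", "M-SZA"],
            "hosp_all_future": ["ALL", "M-PSYCHOSIS", "M-SZ"],
        },
        drugs=[],
        cfe4_published=15,
    ),
    dict(
        probeset="208232_x_at", gene="NRG1", direction="increased",
        discovery_method="DE", discovery_percent=65.8, discovery_points=4,
        cfg_points=4, validation_p=6.66e-01, validation_stepwise=True,
        validation_points=2,
        step4_strata={
            "state_sas4": ["M-MDD", "M-BP"],
            "state_stai": ["F-BP", "M-PSYCHOSIS", "M-SZ", "M-SZA"],
            "hosp_first_year": [],
            "hosp_all_future": ["ALL", "M", "M-BP", "M-PSYCHOSIS", "M-SZA"],
        },
        drugs=["Ketamine", "Antipsychotics", "Valproate", "Lithium"],
        cfe4_published=15,
    ),
    dict(
        probeset="207332_s_at", gene="TFRC", direction="decreased",
        discovery_method="DE", discovery_percent=56.0, discovery_points=4,
        cfg_points=2, validation_p=7.11e-01, validation_stepwise=True,
        validation_points=2,
        step4_strata={
            "state_sas4": ["F", "F-PSYCHOSIS", "F-SZA"],
            "state_stai": ["F-BP"],
            "hosp_first_year": ["M-PTSD"],
            "hosp_all_future": ["ALL", "M", "M-SZA"],
        },
        drugs=["Valproate"],
        cfe4_published=15,
    ),
]


def panel_frame() -> pd.DataFrame:
    """Reference panel as a DataFrame, one row per probeset."""
    return pd.DataFrame(TOP19_PANEL).set_index("probeset")


def panel_directions() -> dict[str, str]:
    """Probeset -> direction of change in high anxiety."""
    return {row["probeset"]: row["direction"] for row in TOP19_PANEL}


def panel_genes() -> dict[str, str]:
    """Probeset -> gene symbol (two probesets share NTRK3)."""
    return {row["probeset"]: row["gene"] for row in TOP19_PANEL}


def reference_drug_table() -> pd.DataFrame:
    """Drug-gene modulation table implied by the reference panel.

    Every drug listed for a biomarker modulates it opposite to its high-anxiety
    direction, so an 'increased' marker is decreased by its listed drugs and
    vice versa. Returns one row per unique (drug, gene) pair with columns
    ``drug``, ``gene``, ``modulation`` ('increases'/'decreases').
    """
    rows = []
    for row in TOP19_PANEL:
        mod = "decreases" if row["direction"] == "increased" else "increases"
        for drug in row["drugs"]:
            rows.append({"drug": drug, "gene": row["gene"], "modulation": mod})
    table = pd.DataFrame(rows, columns=["drug", "gene", "modulation"])
    return table.drop_duplicates(["drug", "gene"]).reset_index(drop=True)
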