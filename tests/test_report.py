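"""Digitized clinician report: thresholds, percentiles, drug matching."""

import numpy as np
import pandas as pd
import pytest

from anxiomark.reference import (TOP19_PANEL, panel_directions, panel_genes,
                                 reference_drug_table)
from anxiomark.report import (ThresholdEntry, clinician_report,
                              compute_thresholds, digitize_biomarker,
                              digitize_panel, drug_coverage,
                              drug_match_percentile, render_report_text,
                              report_to_json, risk_percentile)


def entry(direction="increased", high=1.0, low=-1.0, ps="p"):
    return ThresholdEntry(ps, direction, high, low)


class TestDigitize:
    @pytest.mark.parametrize("z, expected", [
        (1.5, 1.0), (1.0, 1.0), (0.0, 0.5), (-1.0, 0.0), (-2.0, 0.0)])
    def test_increased(self, z, expected):
        assert digitize_biomarker(z, entry()) == expected

    @pytest.mark.parametrize("z, expected", [
        (-1.5, 1.0), (-1.0, 1.0), (0.0, 0.5), (1.0, 0.0), (2.0, 0.0)])
    def test_decreased_mirrored(self, z, expected):
        assert digitize_biomarker(z, entry("decreased", high=-1.0, low=1.0)) \
            == expected

    def test_non_concordant_is_excluded(self):
        bad = entry(high=-1.0, low=1.0)  # increased but high mean below low
        with pytest.raises(ValueError, match="concordant"):
            digitize_biomarker(0.0, bad)
        scores, excluded = digitize_panel({"p": 0.0}, {"p": bad})
        assert scores == {} and excluded == ["p"]

    def test_monotone_in_z(self):
        zs = np.linspace(-3, 3, 61)
        scores = [digitize_biomarker(z, entry()) for z in zs]
        assert all(b >= a for a, b in zip(scores, scores[1:]))
        assert set(scores) == {0.0, 0.5, 1.0}


class TestRiskPercentile:
    def test_bounds(self):
        assert risk_percentile([1.0] * 19) == 100.0
        assert risk_percentile([0.0] * 19) == 0.0

    def test_hand_arithmetic(self):
        scores = [1.0] * 15 + [0.5] * 4
        assert risk_percentile(scores) == pytest.approx(100 * 17 / 19)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            risk_percentile([])


class TestDrugMatch:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["drug", "gene", "modulation"])

    def test_full_match(self):
        scores = {"p1": 1.0, "p2": 1.0}
        table = self._table([("d", "G1", "decreases"), ("d", "G2", "decreases")])
        genes = {"p1": "G1", "p2": "G2"}
        dirs = {"p1": "increased", "p2": "increased"}
        assert drug_match_percentile(scores, table, genes, dirs)["d"] == 100.0

    def test_no_match(self):
        scores = {"p1": 1.0}
        table = self._table([("d", "OTHER", "decreases")])
        out = drug_match_percentile(scores, table, {"p1": "G1"},
                                    {"p1": "increased"})
        assert out["d"] == 0.0

    def test_hand_arithmetic(self):
        scores = {"p1": 1.0, "p2": 0.5, "p3": 0.5}
        table = self._table([("d", "G1", "decreases"), ("d", "G2", "decreases")])
        genes = {f"p{i}": f"G{i}" for i in (1, 2, 3)}
        dirs = {f"p{i}": "increased" for i in (1, 2, 3)}
        assert drug_match_percentile(scores, table, genes, dirs)["d"] \
            == pytest.approx(100 * 1.5 / 3)

    def test_zero_denominator_is_missing(self):
        scores = {"p1": 0.0}
        table = self._table([("d", "G1", "decreases")])
        out = drug_match_percentile(scores, table, {"p1": "G1"},
                                    {"p1": "increased"})
        assert out["d"] is None


class TestDrugCoverage:
    def test_reference_valproate(self):
        """Valproate covers 6 of the panel's 18 unique genes: 33.33%."""
        cov = drug_coverage(panel_genes(),
                            {r["gene"]: r["direction"] for r in TOP19_PANEL},
                            reference_drug_table())
        assert cov["Valproate"] == pytest.approx(100 * 6 / 18, abs=0.01)

    def test_full_and_absent(self):
        genes = {"p1": "G1", "p2": "G2"}
        dirs = {"G1": "increased", "G2": "decreased"}
        table = pd.DataFrame([("d", "G1", "decreases"), ("d", "G2", "increases")],
                             columns=["drug", "gene", "modulation"])
        cov = drug_coverage(genes, dirs, table)
        assert cov["d"] == 100.0
        assert "absent" not in cov

    def test_duplicate_probesets_dedup(self):
        genes = {"p1": "G1", "p1b": "G1", "p2": "G2"}
        dirs = {"G1": "increased", "G2": "increased"}
        table = pd.DataFrame([("d", "G1", "decreases")],
                             columns=["drug", "gene", "modulation"])
        assert drug_coverage(genes, dirs, table)["d"] == pytest.approx(50.0)

    def test_empty_panel_is_error(self):
        with pytest.raises(ValueError):
            drug_coverage({}, {}, pd.DataFrame(columns=["drug", "gene",
                                                        "modulation"]))


class TestClinicianReport:
    def _inputs(self):
        directions = panel_directions()
        genes = panel_genes()
        sign = {ps: (1.0 if d == "increased" else -1.0)
                for ps, d in directions.items()}
        thresholds = {ps: ThresholdEntry(ps, directions[ps], sign[ps] * 0.5,
                                         -sign[ps] * 0.5)
                      for ps in directions}
        return directions, genes, thresholds

    def test_saturated_high_risk_subject(self):
        directions, genes, thresholds = self._inputs()
        z = {ps: (2.0 if directions[ps] == "increased" else -2.0)
             for ps in directions}
        report = clinician_report("HI", z, thresholds, thresholds, thresholds,
                                  reference_drug_table(), genes, directions)
        rp = report["risk_percentiles"]
        assert rp["state"] == 100.0
        assert rp["chronic_combined"] == 100.0
        # clozapine matches 8 of the 19 saturated markers (both NTRK3
        # probesets), the widest coverage in the reference drug table
        top = report["medication_matches"][0]
        assert top["drug"] == "Clozapine"
        assert top["match"] == pytest.approx(100 * 8 / 19)
        matches = {m["drug"]: m["match"] for m in report["medication_matches"]}
        assert matches["Valproate"] == pytest.approx(100 * 6 / 19)

    def test_low_risk_subject(self):
        directions, genes, thresholds = self._inputs()
        z = {ps: (-2.0 if directions[ps] == "increased" else 2.0)
             for ps in directions}
        report = clinician_report("LO", z, thresholds, thresholds, thresholds,
                                  reference_drug_table(), genes, directions)
        assert report["risk_percentiles"]["state"] == 0.0
        assert report["medication_matches"] == []

    def test_report_is_deterministic_json(self):
        directions, genes, thresholds = self._inputs()
        z = {ps: 0.1 for ps in directions}
        args = ("S", z, thresholds, thresholds, thresholds,
                reference_drug_table(), genes, directions)
        assert report_to_json(clinician_report(*args)) \
            == report_to_json(clinician_report(*args))

    def test_text_rendering_mentions_percentiles(self):
        directions, genes, thresholds = self._inputs()
        z = {ps: (2.0 if directions[ps] == "increased" else -2.0)
             for ps in directions}
        report = clinician_report("HI", z, thresholds, thresholds, thresholds,
                                  reference_drug_table(), genes, directions,
                                  nutraceuticals=("Omega-3 fatty acids",))
        text = render_report_text(report)
        assert "100.0 %" in text
        assert "Omega-3 fatty acids" in text


class TestComputeThresholds:
    def test_group_means_and_concordance(self):
        values = pd.DataFrame([[2.0, 2.0, 0.0, 0.0], [0.0, 0.0, 2.0, 2.0]],
                              index=["up", "down"],
                              columns=["h1", "h2", "l1", "l2"])
        th = compute_thresholds(values, ["h1", "h2"], ["l1", "l2"],
                                {"up": "increased", "down": "decreased"})
        assert th["up"].concordant and th["down"].concordant
        assert th["up"].high_group_mean == 2.0
        th_bad = compute_thresholds(values, ["l1", "l2"], ["h1", "h2"],
                                    {"up": "increased", "down": "decreased"})
        assert not th_bad["up"].concordant
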