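"""Data model, file IO, state labeling, and stratified z-scoring."""

import numpy as np
import pandas as pd
import pytest

from anxiomark.cohort import (CohortError, ExpressionMatrix, StateLabel,
                              StratumNormalizer, label_state, read_cohort,
                              write_cohort, zscore_by_stratum)
from anxiomark.simulate import cohort_subset

from conftest import make_record


def _write_toy(tmp_path, expr_rows, meta_rows):
    expr = tmp_path / "expr.csv"
    meta = tmp_path / "meta.csv"
    expr.write_text("\n".join(expr_rows) + "\n")
    meta.write_text("\n".join(meta_rows) + "\n")
    return expr, meta


META_HEADER = "sample_id,subject_id,visit_index,gender,diagnosis,sas4"


class TestReadCohort:
    def test_toy_shape_and_join(self, tmp_path):
        expr, meta = _write_toy(
            tmp_path,
            ["probeset,S1,S2,S3,S4", "p1,1,2,3,4", "p2,5,6,7,8", "p3,9,8,7,6"],
            [META_HEADER, "S1,A,1,M,BP,20", "S2,A,2,M,BP,70",
             "S3,B,1,F,MDD,30", "S4,B,2,F,MDD,80"])
        matrix, records = read_cohort(expr, meta)
        assert matrix.values.shape == (3, 4)
        assert len(records) == 4
        assert [r.sample_id for r in records] == ["S1", "S2", "S3", "S4"]

    def test_unmatched_sample_is_named(self, tmp_path):
        expr, meta = _write_toy(
            tmp_path,
            ["probeset,S1", "p1,1.0"],
            [META_HEADER, "S1,A,1,M,BP,20", "S9,A,2,M,BP,70"])
        with pytest.raises(CohortError, match="S9"):
            read_cohort(expr, meta)

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        expr, meta = _write_toy(
            tmp_path,
            ["probeset,S1,S2", "p1,1.0,oops", "p2,2.0,3.0"],
            [META_HEADER, "S1,A,1,M,BP,20", "S2,A,2,M,BP,70"])
        with pytest.raises(CohortError, match="p1.*S2"):
            read_cohort(expr, meta)

    def test_duplicate_probeset_rejected(self, tmp_path):
        expr, meta = _write_toy(
            tmp_path,
            ["probeset,S1,S2", "p1,1.0,2.0", "p1,3.0,4.0"],
            [META_HEADER, "S1,A,1,M,BP,20", "S2,A,2,M,BP,70"])
        with pytest.raises(CohortError, match="duplicate probeset"):
            read_cohort(expr, meta)

    def test_round_trip_preserves_cohort(self, tmp_path, small_cohort):
        matrix, records, truth = small_cohort
        sub, recs = cohort_subset(matrix, records, truth, "discovery")
        write_cohort(sub, recs, tmp_path / "e.csv", tmp_path / "m.csv",
                     tmp_path / "d.csv")
        back, back_recs = read_cohort(tmp_path / "e.csv", tmp_path / "m.csv",
                                      tmp_path / "d.csv")
        np.testing.assert_allclose(back.values.to_numpy(), sub.values.to_numpy(),
                                   atol=1e-12)
        assert back.detection.equals(sub.detection)
        assert back_recs == recs


class TestStateLabel:
    @pytest.mark.parametrize("sas4, stai, expected", [
        (35.0, None, StateLabel.LOW),
        (40.0, None, StateLabel.LOW),          # boundary inclusive
        (70.0, 60.0, StateLabel.SEVERE),
        (60.0, 55.0, StateLabel.SEVERE),       # both boundaries inclusive
        (70.0, 50.0, StateLabel.HIGH),
        (60.0, None, StateLabel.HIGH),         # missing STAI never SEVERE
        (50.0, 70.0, StateLabel.INTERMEDIATE),
        (40.5, None, StateLabel.INTERMEDIATE),
    ])
    def test_thresholds(self, sas4, stai, expected):
        rec = make_record(sas4=sas4, stai_state=stai)
        assert label_state(rec) is expected

    def test_missing_sas4_is_error(self):
        rec = make_record(sas4=float("nan"))
        with pytest.raises(CohortError, match="missing sas4"):
            label_state(rec)

    def test_order_independent(self, small_cohort):
        _, records, _ = small_cohort
        forward = [label_state(r) for r in records]
        backward = [label_state(r) for r in reversed(records)]
        assert forward == backward[::-1]


class TestZScore:
    def test_single_stratum_closed_form(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0, 2.0, 3.0]], index=["p"],
                                          columns=["S1", "S2", "S3"]))
        recs = [make_record(f"S{i}", "A", i, "M", "BP", 20.0) for i in (1, 2, 3)]
        z = zscore_by_stratum(m, recs)
        np.testing.assert_allclose(z.values.loc["p"], [-1.0, 0.0, 1.0])

    def test_strata_independent_and_pooled_mean_zero(self, toy_matrix, toy_records):
        z = zscore_by_stratum(toy_matrix, toy_records)
        male = z.values[["S1", "S2"]]
        female = z.values[["S3", "S4"]]
        np.testing.assert_allclose(male.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(female.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-12)

    def test_idempotent(self, small_cohort):
        matrix, records, truth = small_cohort
        sub, recs = cohort_subset(matrix, records, truth, "discovery")
        once = zscore_by_stratum(sub, recs)
        twice = zscore_by_stratum(once, recs)
        np.testing.assert_allclose(twice.values.to_numpy(),
                                   once.values.to_numpy(), atol=1e-9)

    def test_singleton_stratum_named_in_error(self, toy_matrix):
        recs = [make_record("S1", "A", 1, "M", "BP", 20.0),
                make_record("S2", "A", 2, "M", "BP", 70.0),
                make_record("S3", "B", 1, "F", "MDD", 30.0),
                make_record("S4", "C", 1, "F", "PTSD", 80.0)]
        with pytest.raises(CohortError, match="F-(MDD|PTSD)"):
            zscore_by_stratum(toy_matrix, recs)

    def test_zero_variance_probeset_warns_and_zeroes(self, toy_matrix, toy_records):
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_by_stratum(toy_matrix, toy_records)
        np.testing.assert_array_equal(z.values.loc["p2"].to_numpy(), 0.0)

    def test_frozen_transform_is_out_of_sample(self, toy_matrix, toy_records):
        norm = StratumNormalizer().fit(toy_matrix, toy_records)
        shifted = ExpressionMatrix(toy_matrix.values + 1.0)
        z = norm.transform(shifted, toy_records)
        base = norm.transform(toy_matrix, toy_records)
        # uniform +1 shift moves every non-degenerate z-score up, it is not
        # re-absorbed by refitting
        assert (z.values.loc["p1"] > base.values.loc["p1"]).all()
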