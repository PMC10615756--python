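"""Synthetic cohort generator: structure, determinism, planted effects."""

import numpy as np
import pytest
from scipy import stats

from anxiomark.cohort import StateLabel, label_state
from anxiomark.discovery import find_diametric_pairs
from anxiomark.simulate import (SimulationConfig, SimulationError,
                                cohort_subset, simulate_cohort,
                                simulate_evidence_table)


def _auc(pos, neg):
    u, _ = stats.mannwhitneyu(pos, neg)
    return u / (len(pos) * len(neg))


class TestStructure:
    def test_same_seed_bit_identical(self, small_config):
        m1, r1, _ = simulate_cohort(small_config)
        m2, r2, _ = simulate_cohort(small_config)
        assert m1.values.equals(m2.values)
        assert m1.detection.equals(m2.detection)
        assert r1 == r2

    def test_discovery_subjects_have_diametric_pairs(self, small_cohort):
        matrix, records, truth = small_cohort
        _, recs = cohort_subset(matrix, records, truth, "discovery")
        by_subject = {}
        for rec in recs:
            by_subject.setdefault(rec.subject_id, []).append(rec)
        for sid, visits in by_subject.items():
            assert find_diametric_pairs(visits), f"{sid} lacks a diametric pair"

    def test_validation_subjects_severe(self, small_cohort):
        matrix, records, truth = small_cohort
        _, recs = cohort_subset(matrix, records, truth, "validation")
        assert all(label_state(r) is StateLabel.SEVERE for r in recs)

    def test_test_cohort_has_followup(self, small_cohort):
        matrix, records, truth = small_cohort
        _, recs = cohort_subset(matrix, records, truth, "test")
        assert all(r.censor_time is not None for r in recs)
        assert any(r.followup_any_future_hosp for r in recs)
        for r in recs:
            if r.time_to_first_hosp is not None:
                assert r.time_to_first_hosp <= r.censor_time + 1e-12

    def test_infeasible_configs_rejected(self):
        with pytest.raises(SimulationError):
            simulate_cohort(SimulationConfig(n_subjects_discovery=0))
        with pytest.raises(SimulationError):
            simulate_cohort(SimulationConfig(n_probesets=5, n_state_markers=4,
                                             n_trait_markers=4))
        with pytest.raises(SimulationError):
            simulate_cohort(SimulationConfig(visits_per_subject={2: 0.5, 3: 0.4}))


class TestPlantedEffects:
    def _low_high_auc(self, config):
        matrix, records, truth = simulate_cohort(config)
        _, recs = cohort_subset(matrix, records, truth, "discovery")
        lows = [r.sample_id for r in recs if label_state(r) is StateLabel.LOW]
        highs = [r.sample_id for r in recs if label_state(r) is StateLabel.HIGH]
        aucs = []
        for ps in sorted(truth.state_marker_ids):
            x = matrix.values.loc[ps]
            pos, neg = x[highs].to_numpy(), x[lows].to_numpy()
            if truth.directions[ps] == "decreased":
                pos, neg = -pos, -neg
            aucs.append(_auc(pos, neg))
        n = len(lows) + len(highs)
        return np.array(aucs), n

    def test_null_effect_gives_chance_auc(self):
        config = SimulationConfig(n_subjects_discovery=60, n_probesets=60,
                                  n_state_markers=10, n_trait_markers=0,
                                  state_effect=0.0, subject_sd=0.0, seed=21)
        aucs, n = self._low_high_auc(config)
        se = np.sqrt(0.25 / (n / 2)) / np.sqrt(len(aucs))
        assert abs(aucs.mean() - 0.5) < 3 * se + 0.02

    def test_binormal_closed_form(self):
        # mean shift d with unit noise on both classes: AUC = Phi(d / sqrt(2))
        d = 1.5
        config = SimulationConfig(n_subjects_discovery=150, n_probesets=60,
                                  n_state_markers=10, n_trait_markers=0,
                                  state_effect=d, subject_sd=0.0, seed=22)
        aucs, _ = self._low_high_auc(config)
        expected = stats.norm.cdf(d / np.sqrt(2))
        assert abs(aucs.mean() - expected) < 0.03

    def test_hospitalization_monotone_in_trait_hazard(self):
        # first-year rate from the first visit is nearly linear in the
        # hazard, unlike the long-horizon event rate which saturates
        rates = []
        for log_hr in (0.0, np.log(4), np.log(16)):
            config = SimulationConfig(
                n_subjects_discovery=4, n_subjects_validation=4,
                n_subjects_test=500, n_probesets=60, n_state_markers=5,
                n_trait_markers=10, trait_log_hazard=log_hr, seed=7)
            matrix, records, truth = simulate_cohort(config)
            _, recs = cohort_subset(matrix, records, truth, "test")
            first = [r for r in recs if r.visit_index == 1]
            rates.append(np.mean([bool(r.followup_first_year_hosp)
                                  for r in first]))
        assert rates[0] < rates[1] < rates[2]


class TestEvidenceTable:
    def test_degenerate_rates(self, small_cohort):
        _, _, truth = small_cohort
        planted = {truth.gene_map[ps]
                   for ps in truth.state_marker_ids | truth.trait_marker_ids}
        full = simulate_evidence_table(truth, sensitivity=1.0,
                                       false_positive_rate=0.0, seed=1)
        assert set(full["gene_symbol"]) == planted
        assert full.groupby("gene_symbol").size().eq(6).all()
        empty = simulate_evidence_table(truth, sensitivity=0.0,
                                        false_positive_rate=0.0, seed=1)
        assert empty.empty

    def test_false_positive_rate_binomial(self):
        config = SimulationConfig(n_subjects_discovery=4, n_subjects_validation=4,
                                  n_subjects_test=4, n_probesets=1010,
                                  n_state_markers=5, n_trait_markers=5, seed=3)
        _, _, truth = simulate_cohort(config)
        table = simulate_evidence_table(truth, sensitivity=0.0,
                                        false_positive_rate=0.05, seed=9)
        # 1000 null genes x 6 categories, each annotated w.p. 0.05
        count = len(table)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000 * 6, 0.05)
        assert lo <= count <= hi

    def test_reproducible_under_seed(self, small_cohort):
        _, _, truth = small_cohort
        t1 = simulate_evidence_table(truth, 0.5, 0.05, seed=4)
        t2 = simulate_evidence_table(truth, 0.5, 0.05, seed=4)
        assert t1.equals(t2)
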