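"""Aggregation, INMB identities, subgroup additivity and delayed-diagnosis
QALY loss."""

import numpy as np
import pandas as pd
import pytest

from crctriage.economics import (
    EconomicsConfig,
    StrategyOutcome,
    SubgroupSpec,
    aggregate,
    incremental,
    inmb,
    qaly_loss_per_delayed_diagnosis,
    subgroup_outcomes,
)
from crctriage.markov import LifeCourseResults
from crctriage.pathway import DiagnosticOutcomes


def make_results(person_ids, cost, qaly, ly=None, deaths=0.0):
    n = len(person_ids)
    return LifeCourseResults(pd.DataFrame({
        "person_id": person_ids,
        "discounted_cost": cost,
        "discounted_qaly": qaly,
        "discounted_ly": ly if ly is not None else qaly,
        "undiscounted_cost": cost,
        "undiscounted_qaly": qaly,
        "undiscounted_ly": ly if ly is not None else qaly,
        "crc_death_probability": deaths,
        "stage_at_diagnosis": "none",
    }))


def make_diag(person_ids, cost=0.0, referred=False, detected=False):
    n = len(person_ids)
    return DiagnosticOutcomes(pd.DataFrame({
        "person_id": person_ids,
        "referred": referred,
        "attended": referred,
        "investigation": "none",
        "crc_detected_usc": detected,
        "crc_diagnosis_delay": 0.0,
        "adenoma_detected": False,
        "ibd_detected_usc": False,
        "ibd_diagnosis_delay": 0.0,
        "short_term_cost": cost,
        "short_term_qaly_loss": 0.0,
        "delayed_dx_cost": 0.0,
    }))


class TestInmb:
    def test_zero(self):
        assert inmb(0.0, 0.0, 20000.0) == 0.0

    def test_headline_two_way_comparison(self):
        """Cost saving of 6.6m with 45 QALYs lost values at +5.7m/million."""
        assert inmb(-6.6e6, -45.0, 20000.0) == pytest.approx(5.7e6)

    def test_pure_cost_offset(self):
        assert inmb(1000.0, 0.1, 20000.0) == pytest.approx(1000.0)


class TestAggregate:
    def test_single_person_scaling(self):
        res = make_results([1], [100.0], [1.0])
        out = aggregate(res, make_diag([1]), EconomicsConfig())
        assert out.cost == pytest.approx(100.0 * 1e6)

    def test_identical_inputs_identical_outcomes(self):
        res = make_results([1, 2], [50.0, 70.0], [1.0, 2.0])
        diag = make_diag([1, 2], cost=10.0)
        a = aggregate(res, diag, EconomicsConfig(), label="A")
        b = aggregate(res, diag, EconomicsConfig(), label="B")
        assert (a.cost, a.qaly, a.ly) == (b.cost, b.qaly, b.ly)

    def test_hand_summed_totals(self):
        cfg = EconomicsConfig(scale=4.0)
        res = make_results([1, 2], [100.0, 200.0], [3.0, 5.0], deaths=[0.1, 0.2])
        diag = make_diag([1, 2], cost=10.0)
        out = aggregate(res, diag, cfg)
        assert out.cost == pytest.approx((100 + 200 + 20) * 2)
        assert out.qaly == pytest.approx(16.0)
        assert out.crc_deaths == pytest.approx(0.6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate(make_results([], [], []), make_diag([]), EconomicsConfig())


class TestIncremental:
    def cfg(self):
        return EconomicsConfig()

    def outcome(self, label, cost, qaly):
        return StrategyOutcome(label, cost, qaly, qaly, 0.0, 10.0, 1.0)

    def test_self_comparison_zero(self):
        a = self.outcome("A", 1e6, 100.0)
        inc = incremental(a, a, self.cfg())
        assert inc.d_cost == 0 and inc.d_qaly == 0 and inc.inmb == 0

    def test_antisymmetry(self):
        a = self.outcome("A", 1e6, 100.0)
        b = self.outcome("B", 2e6, 140.0)
        ab = incremental(a, b, self.cfg())
        ba = incremental(b, a, self.cfg())
        assert ab.inmb == -ba.inmb
        assert ab.d_cost == -ba.d_cost

    def test_inmb_identity_exact(self):
        a = self.outcome("A", 1e6, 100.0)
        b = self.outcome("B", 2e6, 140.0)
        inc = incremental(a, b, self.cfg())
        assert inc.inmb == 20000.0 * inc.d_qaly - inc.d_cost

    def test_dominance_positive_inmb_for_any_wtp(self):
        a = self.outcome("A", 1e6, 140.0)  # cheaper and better
        b = self.outcome("B", 2e6, 100.0)
        for wtp in (0.0, 500.0, 20000.0, 1e6):
            inc = incremental(a, b, EconomicsConfig(wtp=wtp))
            assert inc.inmb > 0
            assert inc.icer_flagged

    def test_scale_mismatch_rejected(self):
        a = self.outcome("A", 1.0, 1.0)
        from dataclasses import replace

        b = replace(self.outcome("B", 1.0, 1.0), scale=500.0)
        with pytest.raises(ValueError):
            incremental(a, b, self.cfg())


class TestSubgroups:
    def test_single_band_equals_population(self, toy_cohort):
        res = make_results([1, 2, 3, 4, 5], [10.0] * 5, [1.0] * 5)
        diag = make_diag([1, 2, 3, 4, 5], cost=5.0)
        cfg = EconomicsConfig()
        spec = SubgroupSpec(age_edges=(18.0, 101.0), sexes=("F", "M"))
        cells = subgroup_outcomes(toy_cohort, res, diag, spec, cfg)
        whole = aggregate(res, diag, cfg, rescale=False)
        assert sum(c.cost for c in cells.values()) == pytest.approx(whole.cost)

    def test_partition_sums_reconcile(self, toy_cohort):
        rng = np.random.default_rng(1)
        res = make_results([1, 2, 3, 4, 5], rng.random(5) * 100, rng.random(5) * 10)
        diag = make_diag([1, 2, 3, 4, 5], cost=7.0)
        cfg = EconomicsConfig()
        cells = subgroup_outcomes(toy_cohort, res, diag, SubgroupSpec(), cfg)
        whole = aggregate(res, diag, cfg, rescale=False)
        for field in ("cost", "qaly", "ly", "usc_referrals"):
            assert sum(getattr(c, field) for c in cells.values()) == pytest.approx(
                getattr(whole, field), abs=1e-9
            )

    def test_default_band_membership(self, toy_cohort):
        res = make_results([1, 2, 3, 4, 5], [1.0] * 5, [1.0] * 5)
        diag = make_diag([1, 2, 3, 4, 5])
        cells = subgroup_outcomes(toy_cohort, res, diag, SubgroupSpec(), EconomicsConfig())
        # ages 42F, 48M, 61F, 74M, 85F
        assert cells[("18-50", "F")].n_simulated == 1
        assert cells[("18-50", "M")].n_simulated == 1
        assert cells[("50-70", "F")].n_simulated == 1
        assert cells[("70-101", "M")].n_simulated == 1
        assert cells[("70-101", "F")].n_simulated == 1

    def test_person_outside_partition_rejected(self, toy_cohort):
        res = make_results([1, 2, 3, 4, 5], [1.0] * 5, [1.0] * 5)
        diag = make_diag([1, 2, 3, 4, 5])
        spec = SubgroupSpec(age_edges=(18.0, 50.0))  # nobody above 50 covered
        with pytest.raises(ValueError, match="outside"):
            subgroup_outcomes(toy_cohort, res, diag, spec, EconomicsConfig())


class TestQalyLossPerDelayedDiagnosis:
    def test_zero_progression_zero_loss(self, flat_tables):
        from crctriage.markov import ModelTables, TransitionParams, run_lifecourse
        from crctriage.disease import BaselineState
        from test_markov import make_diag as diag1, make_person

        tables = ModelTables(
            TransitionParams(stage_progression=(0.0, 0.0, 0.0), fast_stage_progression=(0.0, 0.0, 0.0)),
            flat_tables.survival, flat_tables.life, flat_tables.utility_cost,
        )
        person = make_person(50)
        state = BaselineState(1, "II", "none", False)
        imm = run_lifecourse(person, state, diag1(detected=True), tables, 0.035)
        dly = run_lifecourse(person, state, diag1(delay=1.0), tables, 0.035)
        assert dly.discounted_qaly == pytest.approx(imm.discounted_qaly, abs=1e-12)

    def test_young_lose_more_than_old(self, default_tables):
        """Delayed diagnosis costs more QALYs under 50 than over 70."""
        from crctriage.disease import BaselineState
        from crctriage.markov import run_lifecourse
        from test_markov import make_diag as diag1, make_person

        losses = {}
        for age in (42, 80):
            person = make_person(age)
            state = BaselineState(1, "II", "none", False)
            imm = run_lifecourse(person, state, diag1(detected=True), default_tables, 0.035)
            dly = run_lifecourse(person, state, diag1(delay=0.5), default_tables, 0.035)
            losses[age] = imm.discounted_qaly - dly.discounted_qaly
        assert losses[42] > losses[80] > 0

    def test_mean_over_paired_results(self):
        imm = make_results([1, 2, 3], [0.0] * 3, [10.0, 8.0, 6.0])
        dly = make_results([1, 2, 3], [0.0] * 3, [9.0, 7.5, 6.0])
        loss = qaly_loss_per_delayed_diagnosis(imm, dly, [True, True, False])
        assert loss == pytest.approx((1.0 + 0.5) / 2)

    def test_empty_band_rejected(self):
        imm = make_results([1], [0.0], [1.0])
        with pytest.raises(ValueError):
            qaly_loss_per_delayed_diagnosis(imm, imm, [False])
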