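"""Lifetime model: stage shift during delay, annual-cycle accrual,
conservation, discounting, IBD and adenoma adjustments."""

import math

import numpy as np
import pytest

import crctriage as ct
from crctriage.disease import BaselineState
from crctriage.markov import (
    LifeTable,
    TransitionParams,
    adenoma_conversion_trace,
    adenoma_lifecourse,
    discount,
    ibd_lifecourse_adjustment,
    lifecourse_batch,
    progress_during_delay,
    run_lifecourse,
)
from crctriage.pathway import DelayModel, DiagnosticOutcome
from crctriage.markov import UtilityCostTable, ModelTables, SurvivalTable
from conftest import make_states


def make_person(age, sex="F", pid=1):
    return ct.Person(pid, float(age), sex, 0.0, {}, True)


def make_diag(pid=1, delay=0.0, detected=False, adenoma_detected=False, ibd_detected=False, ibd_delay=0.0):
    return DiagnosticOutcome(
        pid, detected, detected, "colonoscopy" if detected else "none",
        detected, delay, adenoma_detected, ibd_detected, ibd_delay, 0.0, 0.0, 0.0,
    )


class TestDiscount:
    def test_zero_rate(self):
        assert discount(123.0, 5.0, 0.0) == 123.0

    def test_one_year_base_rate(self):
        assert discount(100.0, 1.0, 0.035) == pytest.approx(96.6184, abs=1e-3)

    def test_ten_years_low_rate(self):
        assert discount(50.0, 10.0, 0.015) == pytest.approx(50 / 1.015**10, rel=1e-12)

    def test_floor_convention_within_year_zero(self):
        assert discount(100.0, 0.9, 0.035) == 100.0


class TestStageShift:
    def test_zero_delay_identity(self):
        dist = progress_during_delay("II", 0.0, TransitionParams())
        assert np.allclose(dist, [0, 1, 0, 0])

    def test_stage_iv_absorbing(self):
        dist = progress_during_delay("IV", 5.0, TransitionParams())
        assert np.allclose(dist, [0, 0, 0, 1])

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            progress_during_delay("I", -1.0, TransitionParams())

    def test_against_monte_carlo_oracle(self):
        """Expected stage distribution after 1 year of continuous exposure
        from stage I matches direct simulation of the exponential race."""
        params = TransitionParams(stage_progression=(0.4, 0.35, 0.3))
        expected = progress_during_delay("I", 1.0, params)

        rng = np.random.default_rng(77)
        n = 200_000
        lam = [-math.log(1 - p) for p in params.stage_progression]
        # oracle: sequential exponential sojourns within the 1-year budget
        stage = np.zeros(n, dtype=int)
        remaining = np.full(n, 1.0)
        for k, l in enumerate(lam):
            here = stage == k
            soj = rng.exponential(1.0 / l, n)
            move = here & (soj < remaining)
            remaining = remaining - np.where(here, soj, 0.0)
            stage[move] += 1
        counts = np.bincount(stage, minlength=4) / n
        for s in range(4):
            se = math.sqrt(max(expected[s] * (1 - expected[s]), 1e-12) / n)
            assert abs(counts[s] - expected[s]) < 3 * se + 1e-4, s

    def test_sampled_mode_matches_expected_mode(self):
        params = TransitionParams()
        rng = np.random.default_rng(5)
        samples = [progress_during_delay("I", 1.0, params, mode="sampled", rng=rng) for _ in range(5000)]
        expected = progress_during_delay("I", 1.0, params)
        freq = np.array([samples.count(s) for s in ("I", "II", "III", "IV")]) / 5000
        assert np.allclose(freq, expected, atol=0.03)

    def test_fast_mode_dominates(self):
        params = TransitionParams()
        base = progress_during_delay("I", 0.5, params)
        fast = progress_during_delay("I", 0.5, params, fast=True)
        # fast progression leaves less mass in stage I
        assert fast[0] < base[0]

    def test_fast_must_dominate_base(self):
        with pytest.raises(Exception):
            TransitionParams(stage_progression=(0.5, 0.5, 0.5), fast_stage_progression=(0.4, 0.5, 0.5))


class TestLifecourseClosedForms:
    def test_no_disease_no_mortality_undiscounted(self, flat_tables):
        """Zero mortality to 100 and unit utility gives LY = QALY = 100 - age."""
        q = np.zeros((101, 2))
        q[100] = 1.0
        uc = UtilityCostTable(gen_band_edges=(18.0,), gen_utility=((1.0, 1.0),))
        tables = ModelTables(flat_tables.transitions, flat_tables.survival, LifeTable(q), uc)
        res = run_lifecourse(
            make_person(60), BaselineState(1, "none", "none", False), make_diag(), tables, 0.0
        )
        assert res.undiscounted_ly == pytest.approx(40.0)
        assert res.discounted_qaly == pytest.approx(40.0)

    def test_geometric_series_discounting(self, flat_tables):
        q = np.zeros((101, 2))
        q[100] = 1.0
        uc = UtilityCostTable(gen_band_edges=(18.0,), gen_utility=((1.0, 1.0),))
        tables = ModelTables(flat_tables.transitions, flat_tables.survival, LifeTable(q), uc)
        r = 0.035
        res = run_lifecourse(
            make_person(90), BaselineState(1, "none", "none", False), make_diag(), tables, r
        )
        expected = sum(1 / (1 + r) ** t for t in range(10))
        assert res.discounted_qaly == pytest.approx(expected, rel=1e-12)

    def test_delay_harm_direction(self, flat_tables):
        """A stage-II case delayed by one year has strictly lower QALY and
        higher CRC death probability than the same case diagnosed at once."""
        person = make_person(60)
        state = BaselineState(1, "II", "none", False)
        immediate = run_lifecourse(person, state, make_diag(delay=0.0, detected=True), flat_tables, 0.035)
        delayed = run_lifecourse(person, state, make_diag(delay=1.0), flat_tables, 0.035)
        assert delayed.discounted_qaly < immediate.discounted_qaly
        assert delayed.crc_death_probability > immediate.crc_death_probability

    def test_delay_harm_monotone_in_delay(self, flat_tables):
        person = make_person(55)
        state = BaselineState(1, "I", "none", False)
        qalys, deaths = [], []
        for d in (0.0, 0.25, 0.5, 1.0, 2.0):
            r = run_lifecourse(person, state, make_diag(delay=d), flat_tables, 0.035)
            qalys.append(r.discounted_qaly)
            deaths.append(r.crc_death_probability)
        assert np.all(np.diff(qalys) < 0)
        assert np.all(np.diff(deaths) > 0)

    def test_qaly_bounded_by_ly(self, flat_tables):
        for stage in ("none", "I", "IV"):
            state = BaselineState(1, stage, "none", False)
            r = run_lifecourse(make_person(45), state, make_diag(delay=0.5 if stage != "none" else 0.0), flat_tables, 0.035)
            assert 0 <= r.discounted_qaly <= r.discounted_ly
            assert r.discounted_ly <= r.undiscounted_ly


class TestGoldenHandComputation:
    def test_stage_ii_case_age_98_exact(self, flat_tables):
        """Two-cycle trace checked against explicit spreadsheet arithmetic."""
        r = 0.035
        res = run_lifecourse(
            make_person(98), BaselineState(1, "II", "none", False),
            make_diag(detected=True), flat_tables, r,
        )
        # cycle 0 (age 98, year-1 phase): occupancy 1 in stage II
        # accrue: ly 1, qaly 0.85*0.8, cost 2000; CRC death 0.05 (+500 terminal)
        # survivors 0.95, other-cause 0.1 -> occupancy 0.855
        occ1 = (1 - 0.05) * (1 - 0.1)
        die2 = occ1 * 0.05
        ly = 1 + occ1 / 1.035
        qaly = 0.85 * 0.8 + occ1 * 0.9 * 0.8 / 1.035
        cost = 2000 + 0.05 * 500 + (occ1 * 200 + die2 * 500) / 1.035
        death = 0.05 + die2
        assert res.discounted_ly == pytest.approx(ly, abs=1e-9)
        assert res.discounted_qaly == pytest.approx(qaly, abs=1e-9)
        assert res.discounted_cost == pytest.approx(cost, abs=1e-9)
        assert res.crc_death_probability == pytest.approx(death, abs=1e-12)

    def test_toy_cohort_batch_matches_single_runs(self, toy_cohort, flat_tables):
        """The vectorised batch engine equals person-by-person runs exactly."""
        crc = ["I", "none", "II", "IV", "none"]
        states = make_states(toy_cohort, crc=crc)
        import pandas as pd
        from crctriage.pathway import DiagnosticOutcomes

        delays = [0.0, 0.0, 0.7, 1.5, 0.0]
        diag = DiagnosticOutcomes(pd.DataFrame({
            "person_id": toy_cohort.df["id"],
            "referred": [True, False, False, False, False],
            "attended": [True, False, False, False, False],
            "investigation": ["colonoscopy", "none", "none", "none", "none"],
            "crc_detected_usc": [True, False, False, False, False],
            "crc_diagnosis_delay": delays,
            "adenoma_detected": False,
            "ibd_detected_usc": False,
            "ibd_diagnosis_delay": 0.0,
            "short_term_cost": 0.0,
            "short_term_qaly_loss": 0.0,
            "delayed_dx_cost": 0.0,
        }))
        batch = lifecourse_batch(toy_cohort, states, diag, flat_tables, 0.035)
        for i, (person, rec) in enumerate(zip(toy_cohort.persons(), states.records())):
            single = run_lifecourse(person, rec, make_diag(pid=person.id, delay=delays[i], detected=(i == 0)), flat_tables, 0.035)
            assert batch.df["discounted_qaly"].iloc[i] == pytest.approx(single.discounted_qaly, abs=1e-9)
            assert batch.df["discounted_cost"].iloc[i] == pytest.approx(single.discounted_cost, abs=1e-9)
            assert batch.df["crc_death_probability"].iloc[i] == pytest.approx(single.crc_death_probability, abs=1e-12)


class TestConservation:
    def test_occupancy_mass_sums_to_one_each_cycle(self, toy_cohort, flat_tables):
        states = make_states(toy_cohort, crc=["I", "II", "III", "IV", "I"])
        import pandas as pd
        from crctriage.pathway import DiagnosticOutcomes

        diag = DiagnosticOutcomes(pd.DataFrame({
            "person_id": toy_cohort.df["id"],
            "referred": False, "attended": False, "investigation": "none",
            "crc_detected_usc": False,
            "crc_diagnosis_delay": [0.1, 0.5, 1.0, 1.9, 2.0],
            "adenoma_detected": False, "ibd_detected_usc": False,
            "ibd_diagnosis_delay": 0.0, "short_term_cost": 0.0,
            "short_term_qaly_loss": 0.0, "delayed_dx_cost": 0.0,
        }))
        _, mass = lifecourse_batch(toy_cohort, states, diag, flat_tables, 0.035, record_mass=True)
        for cycle_mass in mass:
            assert np.allclose(cycle_mass, 1.0, atol=1e-9)


class TestSurvivalTable:
    def test_years_beyond_ten_reuse_year_ten(self, default_tables):
        s = default_tables.survival
        a = s.lookup(np.array([1]), np.array([0]), np.array([65.0]), np.array([10]))
        b = s.lookup(np.array([1]), np.array([0]), np.array([65.0]), np.array([25]))
        assert np.array_equal(a, b)

    def test_round_trip_through_dataframe(self, default_tables):
        df = default_tables.survival.to_dataframe()
        back = SurvivalTable.from_dataframe(df)
        assert np.allclose(back.probs, default_tables.survival.probs)
        assert back.band_edges == default_tables.survival.band_edges

    def test_missing_key_rejected(self, default_tables):
        df = default_tables.survival.to_dataframe().iloc[:-1]
        with pytest.raises(Exception, match="missing"):
            SurvivalTable.from_dataframe(df)


class TestIBDAdjustment:
    def test_scenario_off_zero_deltas(self, toy_cohort, flat_tables):
        states = make_states(toy_cohort, ibd=[True] * 5)
        import pandas as pd
        from crctriage.pathway import DiagnosticOutcomes, ScenarioFlags

        diag = DiagnosticOutcomes(pd.DataFrame({
            "person_id": toy_cohort.df["id"], "referred": False, "attended": False,
            "investigation": "none", "crc_detected_usc": False, "crc_diagnosis_delay": 0.0,
            "adenoma_detected": False, "ibd_detected_usc": False,
            "ibd_diagnosis_delay": 1.34, "short_term_cost": 0.0,
            "short_term_qaly_loss": 0.0, "delayed_dx_cost": 0.0,
        }))
        off = lifecourse_batch(toy_cohort, states, diag, flat_tables, 0.035, ScenarioFlags())
        no_ibd = lifecourse_batch(toy_cohort, make_states(toy_cohort), diag, flat_tables, 0.035, ScenarioFlags())
        assert np.allclose(off.df["discounted_cost"], no_ibd.df["discounted_cost"])

    def test_complicated_costlier_than_routine(self, flat_tables):
        age = np.array([60])
        sex = np.array([0])
        flags = np.array([True])
        c_routine, q_routine = ibd_lifecourse_adjustment(age, sex, flags, np.array([True]), flat_tables, 0.035)
        c_compl, q_compl = ibd_lifecourse_adjustment(age, sex, flags, np.array([False]), flat_tables, 0.035)
        assert c_compl[0] > c_routine[0] > 0
        assert q_compl[0] < q_routine[0] < 0

    def test_hand_summed_delta_age_98(self, flat_tables):
        """Two-cycle annuity: delta = cost * (1 + 0.9/1.035), utility scaled."""
        c, q = ibd_lifecourse_adjustment(
            np.array([98]), np.array([0]), np.array([True]), np.array([False]), flat_tables, 0.035
        )
        annuity = 1 + 0.9 / 1.035
        uc = flat_tables.utility_cost
        assert c[0] == pytest.approx(uc.ibd_cost["complicated"] * annuity, abs=1e-9)
        assert q[0] == pytest.approx((uc.ibd_utility_mult["complicated"] - 1) * 0.8 * annuity, abs=1e-9)


class TestAdenomaLifecourse:
    def test_conversion_trace_enumeration(self):
        p = 0.3
        params = TransitionParams(adenoma_progression=(0.0, p))
        conv = adenoma_conversion_trace("high_risk", params, 2)
        assert conv.sum() == pytest.approx(1 - (1 - p) ** 2, rel=1e-12)

    def test_low_risk_must_pass_through_high_risk(self):
        params = TransitionParams(adenoma_progression=(0.5, 0.5))
        conv = adenoma_conversion_trace("low_risk", params, 2)
        assert conv[0] == 0.0 and conv[1] == pytest.approx(0.25)

    def test_zero_progression_zero_deltas(self, flat_tables):
        tables = ModelTables(
            TransitionParams(adenoma_progression=(0.0, 0.0)),
            flat_tables.survival, flat_tables.life, flat_tables.utility_cost,
        )
        c, q, ly, d = adenoma_lifecourse(
            np.array([60]), np.array([0]), np.array(["high_risk"], dtype=object),
            tables, 0.035, DelayModel(),
        )
        assert c[0] == 0 and q[0] == 0 and d[0] == 0

    def test_undetected_high_risk_adenoma_causes_harm(self, flat_tables):
        c, q, ly, d = adenoma_lifecourse(
            np.array([55]), np.array([1]), np.array(["high_risk"], dtype=object),
            flat_tables, 0.035, DelayModel(),
        )
        assert c[0] > 0 and q[0] < 0 and d[0] > 0
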