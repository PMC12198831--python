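"""Short-term diagnostic model: delays, costs, detection and the
common-random-numbers pairing contract."""

import numpy as np
import pytest

import crctriage as ct
from crctriage.pathway import (
    DelayModel,
    PathwayParams,
    ScenarioFlags,
    colonoscopy_harm_qaly,
    delay_quantile,
    draw_pathway_uniforms,
    investigation_assignment,
    run_pathway,
    sample_delay,
)
from crctriage.population import ConfigurationError
from conftest import make_states


def perfect_params(**kw) -> PathwayParams:
    base = dict(
        uptake_probability=1.0,
        ctc_fraction=0.0,
        colonoscopy_sensitivity={"crc": 1.0, "hr_adenoma": 1.0, "lr_adenoma": 1.0, "ibd": 1.0},
    )
    base.update(kw)
    return PathwayParams(**base)


class TestDelayModel:
    def test_draws_within_range(self, rng):
        d = sample_delay(DelayModel(), rng, size=100_000)
        assert d.min() >= 2 / 52 and d.max() <= 2.0

    def test_mean_three_months(self, rng):
        d = sample_delay(DelayModel(), rng, size=100_000)
        assert abs(d.mean() - 0.25) < 0.005

    def test_degenerate_model(self, rng):
        d = sample_delay(DelayModel(mean=0.25, min=0.25, max=0.25), rng, size=100)
        assert np.all(d == 0.25)

    def test_infeasible_mean_rejected(self):
        with pytest.raises(ConfigurationError):
            DelayModel(mean=3.0)

    def test_doubled_mean_scenario_value(self, rng):
        d = sample_delay(DelayModel(mean=0.5), rng, size=100_000)
        assert abs(d.mean() - 0.5) < 0.01

    def test_quantile_monotone(self):
        u = np.linspace(0.001, 0.999, 100)
        q = delay_quantile(DelayModel(), u)
        assert np.all(np.diff(q) >= 0)


class TestInvestigationAssignment:
    def test_extremes(self, rng):
        assert investigation_assignment(PathwayParams(ctc_fraction=0.0), rng) == "colonoscopy"
        assert investigation_assignment(PathwayParams(ctc_fraction=1.0), rng) == "ctc"

    def test_binomial_share(self, rng):
        out = investigation_assignment(PathwayParams(ctc_fraction=0.3), rng, size=100_000)
        share = (out == "ctc").mean()
        assert abs(share - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 100_000)


class TestColonoscopyHarm:
    def test_full_day_scenario(self):
        harm = colonoscopy_harm_qaly(ScenarioFlags(colonoscopy_harm_full_day=True), PathwayParams())
        assert harm == 1.0 / 365.25

    def test_zero_complications(self):
        harm = colonoscopy_harm_qaly(ScenarioFlags(), PathwayParams(complication_probability=0.0))
        assert harm == 0.0

    def test_expected_decrement(self):
        p = PathwayParams(complication_probability=0.01, complication_qaly_decrement=0.3)
        assert colonoscopy_harm_qaly(ScenarioFlags(), p) == pytest.approx(0.003)


class TestRunPathway:
    def test_perfect_detection_limit(self, toy_cohort, rng):
        states = make_states(toy_cohort, crc=["I", "II", "none", "III", "IV"])
        out = run_pathway(
            toy_cohort,
            states,
            np.ones(5, dtype=bool),
            ct.Strategy(ct.StrategyKind.REFER_ALL),
            perfect_params(),
            DelayModel(),
            rng=rng,
        )
        crc = states.has_crc
        assert out.df["crc_detected_usc"].to_numpy()[crc].all()
        assert (out.df["crc_diagnosis_delay"].to_numpy()[crc] == 0).all()

    def test_non_referred_cost_is_gp_plus_fit(self, toy_cohort, rng):
        states = make_states(toy_cohort)
        p = PathwayParams()
        out = run_pathway(
            toy_cohort,
            states,
            np.zeros(5, dtype=bool),
            ct.Strategy(ct.StrategyKind.FIT, 10.0),
            p,
            DelayModel(),
            rng=rng,
        )
        assert np.allclose(out.df["short_term_cost"], p.cost_gp_appointment + p.cost_fit)

    def test_risk_strategy_charges_algorithm_and_fbc(self, toy_cohort, rng):
        # person 2 lacks a recent blood count: pays 8.38 + 0.01 on top
        states = make_states(toy_cohort)
        p = PathwayParams()
        out = run_pathway(
            toy_cohort,
            states,
            np.zeros(5, dtype=bool),
            ct.Strategy(ct.StrategyKind.COX_RISK, 0.01),
            p,
            DelayModel(),
            rng=rng,
        )
        base = p.cost_gp_appointment + p.cost_fit
        costs = out.df["short_term_cost"].to_numpy()
        assert costs[1] == pytest.approx(base + 8.38 + 0.01)
        assert costs[0] == pytest.approx(base + 0.01)  # has a recent FBC

    def test_cost_floor_invariant(self, small_population, rng):
        n = len(small_population)
        states = make_states(small_population)
        p = PathwayParams()
        out = run_pathway(
            small_population,
            states,
            np.random.default_rng(5).random(n) < 0.3,
            ct.Strategy(ct.StrategyKind.FIT, 10.0),
            p,
            DelayModel(),
            rng=rng,
        )
        assert (out.df["short_term_cost"] >= p.cost_gp_appointment + p.cost_fit - 1e-12).all()

    def test_strategy_cost_ordering_exact(self, small_population, rng):
        """With identical referral sets, a risk-score strategy costs exactly
        n * algorithm cost + (persons lacking a recent FBC) * FBC cost more."""
        n = len(small_population)
        states = make_states(small_population)
        draws = draw_pathway_uniforms(n, np.random.default_rng(9))
        p = PathwayParams()
        referrals = np.ones(n, dtype=bool)
        fit = run_pathway(
            small_population, states, referrals, ct.Strategy(ct.StrategyKind.FIT, 0.0),
            p, DelayModel(), draws=draws,
        )
        risk = run_pathway(
            small_population, states, referrals, ct.Strategy(ct.StrategyKind.COX_RISK, 0.0),
            p, DelayModel(), draws=draws,
        )
        lacking = int((~small_population.df["has_recent_fbc"]).sum())
        diff = risk.df["short_term_cost"].sum() - fit.df["short_term_cost"].sum()
        assert diff == pytest.approx(n * p.cost_algorithm + lacking * p.cost_fbc, abs=1e-6)

    def test_common_random_numbers_pair_identical_persons(self, small_population):
        """Persons with the same referral status under two strategies get
        bit-identical outcomes."""
        n = len(small_population)
        rng = np.random.default_rng(21)
        crc = np.where(rng.random(n) < 0.05, "II", "none")
        states = make_states(small_population, crc=list(crc))
        draws = draw_pathway_uniforms(n, np.random.default_rng(3))
        p = PathwayParams()
        ref_a = small_population.df["fit"].to_numpy() >= 10
        ref_b = small_population.df["fit"].to_numpy() >= 40
        out_a = run_pathway(small_population, states, ref_a, ct.Strategy(ct.StrategyKind.FIT, 10.0), p, DelayModel(), draws=draws)
        out_b = run_pathway(small_population, states, ref_b, ct.Strategy(ct.StrategyKind.FIT, 40.0), p, DelayModel(), draws=draws)
        same = ref_a == ref_b
        cols = ["crc_detected_usc", "crc_diagnosis_delay", "short_term_cost", "delayed_dx_cost"]
        for c in cols:
            assert (out_a.df.loc[same, c].to_numpy() == out_b.df.loc[same, c].to_numpy()).all(), c

    def test_delayed_cases_accrue_delayed_costs(self, toy_cohort, rng):
        states = make_states(toy_cohort, crc=["I", "none", "II", "none", "none"])
        p = PathwayParams(emergency_fraction_delayed=1.0)
        out = run_pathway(
            toy_cohort, states, np.zeros(5, dtype=bool),
            ct.Strategy(ct.StrategyKind.FIT, 1e9), p, DelayModel(), rng=rng,
        )
        delayed = out.df["delayed_dx_cost"].to_numpy()
        expected = p.cost_colonoscopy + 2 * p.cost_extra_gp + p.cost_emergency
        assert delayed[0] == pytest.approx(expected)
        assert delayed[2] == pytest.approx(expected)
        assert (delayed[[1, 3, 4]] == 0).all()

    def test_ibd_delay_applied_when_not_detected(self, toy_cohort, rng):
        states = make_states(toy_cohort, ibd=[True, False, True, False, False])
        out = run_pathway(
            toy_cohort, states, np.zeros(5, dtype=bool),
            ct.Strategy(ct.StrategyKind.FIT, 1e9), PathwayParams(), DelayModel(), rng=rng,
        )
        d = out.df["ibd_diagnosis_delay"].to_numpy()
        assert d[0] == pytest.approx(1.34) and d[2] == pytest.approx(1.34)
        assert (d[[1, 3, 4]] == 0).all()

    def test_ibd_detected_at_usc_only_when_scenario_active(self, toy_cohort):
        states = make_states(toy_cohort, ibd=[True] * 5)
        draws = draw_pathway_uniforms(5, np.random.default_rng(2))
        common = dict(
            referrals=np.ones(5, dtype=bool),
            strategy=ct.Strategy(ct.StrategyKind.REFER_ALL),
            params=perfect_params(),
            delay_model=DelayModel(),
            draws=draws,
        )
        base = run_pathway(toy_cohort, states, scenario=ScenarioFlags(), **common)
        ibd_on = run_pathway(
            toy_cohort, states, scenario=ScenarioFlags(include_ibd=True), **common
        )
        assert not base.df["ibd_detected_usc"].any()
        assert ibd_on.df["ibd_detected_usc"].all()
        assert (ibd_on.df["ibd_diagnosis_delay"] == 0).all()

    def test_referral_vector_mismatch_rejected(self, toy_cohort, rng):
        states = make_states(toy_cohort)
        with pytest.raises(ValueError):
            run_pathway(
                toy_cohort, states, np.ones(3, dtype=bool),
                ct.Strategy(ct.StrategyKind.REFER_ALL), PathwayParams(), DelayModel(), rng=rng,
            )
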