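"""End-to-end evaluation of referral strategies on one simulated cohort.

Chains the stages: population generation -> risk-model calibration and
scoring -> baseline disease allocation -> short-term diagnostic pathway ->
lifetime model -> per-strategy aggregation.  All strategies share the same
cohort, baseline truth and uniform draws (common random numbers), so
between-strategy differences reflect the referral rule alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .population import Population, PopulationConfig, generate_population
from .risk import Strategy, StrategyKind, predict_risk, stratify
from .disease import BaselineStates, DiseasePrevalenceConfig, allocate_baseline_states
from .pathway import (
    DelayModel,
    DiagnosticOutcomes,
    PathwayDraws,
    PathwayParams,
    ScenarioFlags,
    draw_pathway_uniforms,
    run_pathway,
)
from .markov import LifeCourseResults, ModelTables, lifecourse_batch
from .economics import EconomicsConfig, StrategyOutcome, aggregate
from . import defaults

__all__ = ["ModelBundle", "Cohort", "StrategyEvaluation", "prepare_cohort", "evaluate_strategy", "evaluate_strategies"]


@dataclass(frozen=True)
class ModelBundle:
    """Every model input needed to evaluate strategies on a cohort."""

    population: PopulationConfig
    disease: DiseasePrevalenceConfig
    pathway: PathwayParams
    delay: DelayModel
    tables: ModelTables
    econ: EconomicsConfig
    scenario: ScenarioFlags = ScenarioFlags()
    risk_model_kind: str = "cox"  # "cox" or "logistic"
    cox_model: object | None = None
    logistic_model: object | None = None
    prevalence_target: float | None = defaults.VALIDATION_PREVALENCE

    @classmethod
    def default(cls, **overrides) -> "ModelBundle":
        base = cls(
            population=defaults.validation_population_config(),
            disease=defaults.default_disease_config(),
            pathway=defaults.default_pathway_params(),
            delay=defaults.default_delay_model(),
            tables=defaults.default_tables(),
            econ=EconomicsConfig(),
            cox_model=defaults.default_cox_model(),
            logistic_model=defaults.default_logistic_model(),
        )
        return replace(base, **overrides) if overrides else base

    def active_model(self, calibrated_cox=None, calibrated_logistic=None):
        if self.risk_model_kind == "cox":
            return calibrated_cox if calibrated_cox is not None else self.cox_model
        if self.risk_model_kind == "logistic":
            return calibrated_logistic if calibrated_logistic is not None else self.logistic_model
        raise ValueError(f"unknown risk model kind '{self.risk_model_kind}'")


@dataclass
class Cohort:
    """A simulated cohort with everything strategies share."""

    population: Population
    risks: np.ndarray
    baseline_states: BaselineStates
    draws: PathwayDraws
    cox_model: object
    logistic_model: object
    bundle: ModelBundle

    def model_for(self, strategy: Strategy):
        if strategy.kind is StrategyKind.COX_RISK:
            return self.cox_model
        if strategy.kind is StrategyKind.LOGISTIC_RISK:
            return self.logistic_model
        return None


@dataclass
class StrategyEvaluation:
    strategy: Strategy
    outcome: StrategyOutcome
    diagnostics: DiagnosticOutcomes
    lifecourse: LifeCourseResults
    referrals: np.ndarray


def prepare_cohort(bundle: ModelBundle, n: int, seed: int) -> Cohort:
    """Generate the population, calibrate risk, allocate disease, fix draws.

    Sub-streams are derived from ``seed`` so population sampling, disease
    allocation and pathway uniforms are independent; both risk-model forms
    are calibrated to the bundle's prevalence target on this cohort.
    """
    ss = np.random.SeedSequence(seed)
    pop_seed, alloc_seed, draw_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    pop = generate_population(bundle.population.with_n_seed(n, pop_seed))

    cox = bundle.cox_model
    logistic = bundle.logistic_model
    if bundle.prevalence_target is not None:
        cox = defaults.calibrate_cox_model(cox, pop, bundle.prevalence_target)
        logistic = defaults.calibrate_logistic_model(logistic, pop, bundle.prevalence_target)
    active = cox if bundle.risk_model_kind == "cox" else logistic
    risks = np.asarray(predict_risk(active, pop))

    states = allocate_baseline_states(
        pop, risks, bundle.disease, np.random.default_rng(alloc_seed)
    )
    draws = draw_pathway_uniforms(len(pop), np.random.default_rng(draw_seed))
    return Cohort(pop, risks, states, draws, cox, logistic, bundle)


def evaluate_strategy(cohort: Cohort, strategy: Strategy) -> StrategyEvaluation:
    """Short-term + lifetime model for one strategy on a prepared cohort."""
    b = cohort.bundle
    referrals = stratify(cohort.population, strategy, cohort.model_for(strategy))
    diag = run_pathway(
        cohort.population,
        cohort.baseline_states,
        referrals,
        strategy,
        b.pathway,
        b.delay,
        b.scenario,
        draws=cohort.draws,
    )
    extra_cost = (
        b.pathway.cost_colonoscopy
        + b.pathway.extra_gp_appointments_delayed * b.pathway.cost_extra_gp
        + b.pathway.emergency_fraction_delayed * b.pathway.cost_emergency
    )
    life = lifecourse_batch(
        cohort.population,
        cohort.baseline_states,
        diag,
        b.tables,
        b.econ,
        b.scenario,
        b.delay,
        adenoma_crc_extra_cost=extra_cost,
    )
    outcome = aggregate(life, diag, b.econ, label=strategy.label)
    return StrategyEvaluation(strategy, outcome, diag, life, referrals)


def evaluate_strategies(
    bundle: ModelBundle, strategies: list[Strategy], n: int, seed: int
) -> tuple[Cohort, list[StrategyEvaluation]]:
    cohort = prepare_cohort(bundle, n, seed)
    return cohort, [evaluate_strategy(cohort, s) for s in strategies]
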