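"""Scenario grid, run orchestration and report writing.

A scenario is a pure transformation of the base configuration touching only
its documented fields: switching on adenoma/IBD detection consequences,
swapping cohort or risk-model form, adding a full-day colonoscopy harm,
doubling the mean diagnostic delay, applying the fast stage-transition
bounds, moving the discount rate, or charging every patient the blood-count
cost.  ``run_analysis`` executes a configured run end to end and writes
delimited result tables plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import pandas as pd

from .risk import Strategy, StrategyKind
from .economics import incremental
from .pipeline import ModelBundle, evaluate_strategies
from . import defaults

__all__ = ["ScenarioId", "RunConfig", "AnalysisResult", "apply_scenario", "run_analysis", "threshold_sweep"]


class ScenarioId(str, Enum):
    BASE = "base"
    ADENOMAS = "1a_adenomas"
    ADENOMAS_IBD = "1b_adenomas_ibd"
    DERIVATION_POPULATION = "2_derivation_population"
    LOGISTIC_MODEL = "3_logistic_model"
    COLONOSCOPY_HARM = "4_colonoscopy_harm"
    DOUBLED_DELAY = "5a_doubled_delay"
    FAST_TRANSITIONS = "5b_fast_transitions"
    COMBINED_DELAY_FAST = "5c_combined"
    DISCOUNT_HIGH = "6a_discount_5"
    DISCOUNT_LOW = "6b_discount_1_5"
    FULL_FBC_COSTS = "7_colofit_costs_up"


def default_strategies(risk_kind: StrategyKind = StrategyKind.COX_RISK) -> list[Strategy]:
    """Refer-all plus the headline FIT / risk-score threshold pairs."""
    return [
        Strategy(StrategyKind.REFER_ALL),
        Strategy(StrategyKind.FIT, 10.0),
        Strategy(risk_kind, 0.0064),
    ]


@dataclass(frozen=True)
class RunConfig:
    """One fully specified analysis run."""

    bundle: ModelBundle
    strategies: tuple[Strategy, ...]
    scenario_id: ScenarioId = ScenarioId.BASE
    mode: str = "deterministic"  # or "psa"
    n: int = 100_000
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def default(cls, n: int = 100_000, seed: int = 0, **kw) -> "RunConfig":
        return cls(
            bundle=ModelBundle.default(),
            strategies=tuple(default_strategies()),
            n=n,
            seed=seed,
            **kw,
        )

    def fingerprint(self) -> str:
        payload = {
            "scenario": self.scenario_id.value,
            "mode": self.mode,
            "n": self.n,
            "seed": self.seed,
            "strategies": [(s.kind.value, s.threshold) for s in self.strategies],
            "population": self.bundle.population.fingerprint(),
            "econ": (self.bundle.econ.wtp, self.bundle.econ.discount_rate),
            "risk_kind": self.bundle.risk_model_kind,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def apply_scenario(base: RunConfig, scenario_id: ScenarioId | str) -> RunConfig:
    """Return a config with exactly the scenario's documented fields changed."""
    sid = ScenarioId(scenario_id)
    b = base.bundle
    flags = b.scenario

    if sid is ScenarioId.BASE:
        return replace(base, scenario_id=sid)
    if sid is ScenarioId.ADENOMAS:
        b = replace(b, scenario=replace(flags, label=sid.value, include_adenomas=True))
    elif sid is ScenarioId.ADENOMAS_IBD:
        b = replace(
            b, scenario=replace(flags, label=sid.value, include_adenomas=True, include_ibd=True)
        )
    elif sid is ScenarioId.DERIVATION_POPULATION:
        b = replace(
            b,
            population=defaults.derivation_population_config(
                n=b.population.n, seed=b.population.seed
            ),
            prevalence_target=defaults.DERIVATION_PREVALENCE,
            scenario=replace(flags, label=sid.value),
        )
    elif sid is ScenarioId.LOGISTIC_MODEL:
        b = replace(b, risk_model_kind="logistic", scenario=replace(flags, label=sid.value))
    elif sid is ScenarioId.COLONOSCOPY_HARM:
        b = replace(b, scenario=replace(flags, label=sid.value, colonoscopy_harm_full_day=True))
    elif sid is ScenarioId.DOUBLED_DELAY:
        b = replace(b, delay=replace(b.delay, mean=0.5), scenario=replace(flags, label=sid.value))
    elif sid is ScenarioId.FAST_TRANSITIONS:
        b = replace(b, scenario=replace(flags, label=sid.value, fast_transitions=True))
    elif sid is ScenarioId.COMBINED_DELAY_FAST:
        b = replace(
            b,
            delay=replace(b.delay, mean=0.5),
            scenario=replace(flags, label=sid.value, fast_transitions=True),
        )
    elif sid is ScenarioId.DISCOUNT_HIGH:
        b = replace(b, econ=replace(b.econ, discount_rate=0.05), scenario=replace(flags, label=sid.value))
    elif sid is ScenarioId.DISCOUNT_LOW:
        b = replace(b, econ=replace(b.econ, discount_rate=0.015), scenario=replace(flags, label=sid.value))
    elif sid is ScenarioId.FULL_FBC_COSTS:
        b = replace(
            b,
            pathway=replace(b.pathway, fbc_charge_fraction=1.0),
            scenario=replace(flags, label=sid.value),
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown scenario id {scenario_id!r}")

    strategies = base.strategies
    if sid is ScenarioId.LOGISTIC_MODEL:
        strategies = tuple(
            replace(s, kind=StrategyKind.LOGISTIC_RISK, label="")
            if s.kind is StrategyKind.COX_RISK
            else s
            for s in strategies
        )
    return replace(base, bundle=b, scenario_id=sid, strategies=strategies)


@dataclass
class AnalysisResult:
    """Outputs of one deterministic run."""

    config: RunConfig
    outcomes: pd.DataFrame  # one row per strategy
    incrementals: pd.DataFrame  # each strategy vs refer-all (or first strategy)
    per_patient_inmb: pd.DataFrame
    manifest: dict


def _outcome_row(o) -> dict:
    return {
        "strategy": o.label,
        "cost": o.cost,
        "qaly": o.qaly,
        "ly": o.ly,
        "crc_deaths": o.crc_deaths,
        "usc_referrals": o.usc_referrals,
        "usc_crc_diagnoses": o.usc_crc_diagnoses,
    }


def run_analysis(config: RunConfig) -> AnalysisResult:
    """Execute one deterministic analysis and (optionally) write its tables.

    Incremental comparisons are taken against the refer-all arm when
    present (first strategy otherwise); per-patient INMB divides the
    per-million INMB by the reporting scale.
    """
    cohort, evals = evaluate_strategies(
        config.bundle, list(config.strategies), config.n, config.seed
    )
    econ = config.bundle.econ
    outcomes = pd.DataFrame([_outcome_row(e.outcome) for e in evals])

    baseline = next(
        (e for e in evals if e.strategy.kind is StrategyKind.REFER_ALL), evals[0]
    )
    inc_rows = []
    for e in evals:
        if e is baseline:
            continue
        inc = incremental(e.outcome, baseline.outcome, econ)
        inc_rows.append(
            {
                "strategy": inc.label_a,
                "comparator": inc.label_b,
                "inmb": inc.inmb,
                "d_cost": inc.d_cost,
                "d_qaly": inc.d_qaly,
                "d_ly": inc.d_ly,
                "d_usc_diagnoses": inc.d_usc_diagnoses,
                "d_crc_deaths": inc.d_crc_deaths,
                "d_referrals": inc.d_referrals,
            }
        )
    incrementals = pd.DataFrame(inc_rows)
    per_patient = incrementals.assign(
        inmb_per_patient=lambda d: d["inmb"] / econ.scale,
        scenario=config.scenario_id.value,
    )[["scenario", "strategy", "comparator", "inmb_per_patient"]]

    manifest = {
        "config_hash": config.fingerprint(),
        "scenario": config.scenario_id.value,
        "seed": config.seed,
        "n": config.n,
        "strategies": [s.label for s in config.strategies],
        "population_fingerprint": cohort.population.config_fingerprint,
    }
    result = AnalysisResult(config, outcomes, incrementals, per_patient, manifest)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        outcomes.to_csv(out / "strategy_outcomes.csv", index=False)
        incrementals.to_csv(out / "incrementals.csv", index=False)
        per_patient.to_csv(out / "per_patient_inmb.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result


def threshold_sweep(
    config: RunConfig,
    fit_thresholds: list[float],
    risk_thresholds: list[float],
) -> pd.DataFrame:
    """Evaluate FIT and risk-score threshold grids against refer-all.

    Returns one row per (arm, threshold) with outcomes and the incremental
    vs refer-all, sorted by USC CRC diagnoses (descending), ready to plot
    INMB against detection.
    """
    if not fit_thresholds and not risk_thresholds:
        raise ValueError("at least one threshold required")
    risk_kind = (
        StrategyKind.LOGISTIC_RISK
        if config.bundle.risk_model_kind == "logistic"
        else StrategyKind.COX_RISK
    )
    strategies = [Strategy(StrategyKind.REFER_ALL)]
    strategies += [Strategy(StrategyKind.FIT, t) for t in fit_thresholds]
    strategies += [Strategy(risk_kind, t) for t in risk_thresholds]
    cohort, evals = evaluate_strategies(config.bundle, strategies, config.n, config.seed)
    econ = config.bundle.econ
    baseline = evals[0]
    rows = []
    for e in evals:
        inc = incremental(e.outcome, baseline.outcome, econ)
        arm = "refer_all" if e.strategy.kind is StrategyKind.REFER_ALL else (
            "fit" if e.strategy.kind is StrategyKind.FIT else "risk"
        )
        rows.append(
            {
                "arm": arm,
                "threshold": e.strategy.threshold,
                **_outcome_row(e.outcome),
                "inmb_vs_refer_all": inc.inmb,
                "d_cost": inc.d_cost,
                "d_qaly": inc.d_qaly,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("usc_crc_diagnoses", ascending=False)
        .reset_index(drop=True)
    )
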