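"""Default model inputs.

Every default in this module is a clearly labelled SYNTHETIC STAND-IN: the
real aggregate inputs (the originating cohorts' covariate quantiles and
correlations, the published risk-score coefficients, calibrated
natural-history transition probabilities, registry survival, national life
tables, and NHS reference costs) are not public, so shapes and magnitudes
here were chosen once to be
clinically plausible — a right-skewed FIT distribution with roughly 20% of
symptomatic patients at or above 10 µg Hb/g, an older-skewed age profile,
anaemia correlated with high FIT — and are overridable from user files via
:mod:`crctriage.io`.

What is *not* a stand-in: the blood-count cost (8.38 GBP), the algorithm
running cost (0.01 GBP), the 91% recent-blood-count share, the 3-month mean
delay on [2 weeks, 2 years], the 1.34-year IBD delay, the 1.2%/1.5% CRC
prevalence calibration targets, the 20,000 GBP/QALY threshold and the 3.5%
discount rate.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .population import MarginalSpec, PopulationConfig
from .risk import CoxRiskModel, LogisticRiskModel
from .disease import DiseasePrevalenceConfig
from .pathway import DelayModel, PathwayParams
from .markov import (
    LifeTable,
    MAX_AGE,
    ModelTables,
    SurvivalTable,
    TransitionParams,
    UtilityCostTable,
)

__all__ = [
    "VALIDATION_PREVALENCE",
    "DERIVATION_PREVALENCE",
    "validation_population_config",
    "derivation_population_config",
    "default_cox_model",
    "default_logistic_model",
    "calibrate_cox_model",
    "calibrate_logistic_model",
    "default_disease_config",
    "default_pathway_params",
    "default_delay_model",
    "build_default_life_table",
    "build_default_survival_table",
    "default_tables",
]

VALIDATION_PREVALENCE = 0.012
DERIVATION_PREVALENCE = 0.015

_VARIABLES = ("age", "sex", "fit", "haemoglobin", "mcv")

# latent-normal correlations (age, sex[male], FIT, haemoglobin, MCV):
# FIT rises modestly with age, bleeding lesions lower haemoglobin and MCV,
# men have higher haemoglobin.  Verified positive definite.
_CORRELATION = (
    (1.00, 0.05, 0.15, -0.20, 0.05),
    (0.05, 1.00, 0.05, 0.35, 0.05),
    (0.15, 0.05, 1.00, -0.25, -0.15),
    (-0.20, 0.35, -0.25, 1.00, 0.30),
    (0.05, 0.05, -0.15, 0.30, 1.00),
)


def _marginals(fit_grid, age_grid, male_share: float) -> tuple[MarginalSpec, ...]:
    return (
        MarginalSpec("age", age_grid, lower_bound=18.0, upper_bound=100.0),
        MarginalSpec("sex", ((1.0 - male_share, 0.0), (1.0, 1.0)), binary=True),
        MarginalSpec("fit", fit_grid, transform="log", lower_bound=0.0),
        MarginalSpec(
            "haemoglobin",
            ((0.0, 70.0), (0.05, 108.0), (0.25, 128.0), (0.5, 138.0),
             (0.75, 147.0), (0.95, 160.0), (1.0, 190.0)),
        ),
        MarginalSpec(
            "mcv",
            ((0.0, 60.0), (0.05, 78.0), (0.25, 86.0), (0.5, 90.0),
             (0.75, 94.0), (0.95, 99.0), (1.0, 115.0)),
        ),
    )


# right-skewed FIT (µg Hb/g): ~80% of the symptomatic population below the
# 10 µg/g referral threshold
_FIT_GRID_VALIDATION = (
    (0.0, 0.0),
    (0.25, 1.0),
    (0.50, 3.0),
    (0.75, 8.0),
    (0.80, 10.0),
    (0.90, 28.0),
    (0.95, 70.0),
    (0.99, 400.0),
    (1.0, 1200.0),
)

_AGE_GRID_VALIDATION = (
    (0.0, 18.0),
    (0.10, 31.0),
    (0.25, 44.0),
    (0.50, 58.0),
    (0.75, 70.0),
    (0.90, 79.0),
    (1.0, 100.0),
)

# derivation-like cohort: slightly older with a heavier FIT tail
_FIT_GRID_DERIVATION = (
    (0.0, 0.0),
    (0.25, 1.2),
    (0.50, 3.5),
    (0.75, 9.0),
    (0.79, 10.0),
    (0.90, 34.0),
    (0.95, 85.0),
    (0.99, 450.0),
    (1.0, 1400.0),
)

_AGE_GRID_DERIVATION = (
    (0.0, 18.0),
    (0.10, 33.0),
    (0.25, 46.0),
    (0.50, 60.0),
    (0.75, 71.0),
    (0.90, 80.0),
    (1.0, 100.0),
)


def validation_population_config(n: int = 100_000, seed: int = 0) -> PopulationConfig:
    """Validation-style cohort (base case; CRC prevalence target 1.2%)."""
    return PopulationConfig(
        cohort_label="validation",
        marginals=_marginals(_FIT_GRID_VALIDATION, _AGE_GRID_VALIDATION, 0.45),
        correlation=_CORRELATION,
        recent_fbc_probability=0.91,
        n=n,
        seed=seed,
    )


def derivation_population_config(n: int = 100_000, seed: int = 0) -> PopulationConfig:
    """Derivation-style cohort (scenario; CRC prevalence target 1.5%)."""
    return PopulationConfig(
        cohort_label="derivation",
        marginals=_marginals(_FIT_GRID_DERIVATION, _AGE_GRID_DERIVATION, 0.46),
        correlation=_CORRELATION,
        recent_fbc_probability=0.91,
        n=n,
        seed=seed,
    )


# --------------------------------------------------------------------------
# stand-in risk models
# --------------------------------------------------------------------------

_COEFFICIENTS = {
    "age": 0.045,
    "sex": 0.30,
    "fit": 0.78,
    "haemoglobin": -0.020,
    "mcv": -0.030,
}
_TRANSFORMS = {
    "age": "identity",
    "sex": "identity",
    "fit": "log1p",
    "haemoglobin": "identity",
    "mcv": "identity",
}


def default_cox_model(baseline_survival: float = 0.999) -> CoxRiskModel:
    """Synthetic stand-in Cox model; calibrate before use (see below)."""
    return CoxRiskModel(
        coefficients=dict(_COEFFICIENTS),
        covariate_transforms=dict(_TRANSFORMS),
        baseline_survival_at_horizon=baseline_survival,
    )


def default_logistic_model(intercept: float = -8.0) -> LogisticRiskModel:
    """Synthetic stand-in logistic model; calibrate before use (see below)."""
    return LogisticRiskModel(
        intercept=intercept,
        coefficients=dict(_COEFFICIENTS),
        covariate_transforms=dict(_TRANSFORMS),
    )


def calibrate_cox_model(model: CoxRiskModel, pop, target_mean_risk: float) -> CoxRiskModel:
    """Solve the baseline survival so the cohort mean 1-year risk hits target.

    Mirrors the calibration of modelled prevalence to observed 1-year
    incidence: mean over the population of 1 - S0^exp(lp) = target.
    """
    from dataclasses import replace
    from .risk import linear_predictor

    explp = np.exp(linear_predictor(model, pop))

    def gap(log_neg_log_s0: float) -> float:
        s0 = np.exp(-np.exp(log_neg_log_s0))
        return float(np.mean(1.0 - s0**explp)) - target_mean_risk

    sol = optimize.brentq(gap, -30.0, 5.0)
    return replace(model, baseline_survival_at_horizon=float(np.exp(-np.exp(sol))))


def calibrate_logistic_model(
    model: LogisticRiskModel, pop, target_mean_risk: float
) -> LogisticRiskModel:
    """Shift the intercept so the cohort mean risk hits the target."""
    from dataclasses import replace
    from .risk import linear_predictor

    lp = linear_predictor(model, pop)

    def gap(intercept: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(intercept + lp))))) - target_mean_risk

    sol = optimize.brentq(gap, -30.0, 10.0)
    return replace(model, intercept=float(sol))


# --------------------------------------------------------------------------
# disease prevalence, pathway, delay
# --------------------------------------------------------------------------


def default_disease_config() -> DiseasePrevalenceConfig:
    """Stand-in prevalences; IBD is young-skewed and FIT-linked."""
    ibd = []
    for lo, hi, p_lt, p_ge in (
        (18, 30, 0.004, 0.060),
        (30, 40, 0.003, 0.045),
        (40, 50, 0.002, 0.030),
        (50, 60, 0.0015, 0.020),
        (60, 70, 0.001, 0.014),
        (70, 101, 0.001, 0.010),
    ):
        ibd.append((float(lo), float(hi), "lt10", p_lt))
        ibd.append((float(lo), float(hi), "ge10", p_ge))
    return DiseasePrevalenceConfig(
        crc_stage_distribution=(0.25, 0.30, 0.30, 0.15),
        hr_adenoma_prevalence={"ge10": 0.08, "lt10": 0.015},
        lr_adenoma_prevalence=0.10,
        ibd_prevalence=tuple(ibd),
        prevalence_scaling=1.0,
    )


def default_pathway_params() -> PathwayParams:
    return PathwayParams()


def default_delay_model() -> DelayModel:
    return DelayModel()


# --------------------------------------------------------------------------
# life table, survival table, tables bundle
# --------------------------------------------------------------------------


def build_default_life_table() -> LifeTable:
    """Gompertz-style stand-in for a national life table; q(100) = 1."""
    ages = np.arange(MAX_AGE + 1)
    base = np.minimum(3.2e-5 * np.exp(0.093 * ages), 1.0)
    q = np.stack([0.85 * base, 1.15 * base], axis=1)
    q = np.clip(q, 0.0, 1.0)
    q[MAX_AGE, :] = 1.0
    return LifeTable(q)


def build_default_survival_table() -> SurvivalTable:
    """Stand-in registry-style CRC survival: death risk rises with stage and
    age, falls with years since diagnosis."""
    band_edges = (18.0, 60.0, 70.0, 80.0)
    year1 = np.array([0.03, 0.08, 0.18, 0.45])  # by stage
    decline = 0.75 ** np.arange(10)  # by year since dx
    age_mult = np.array([0.85, 1.00, 1.20, 1.45])
    sex_mult = np.array([0.95, 1.05])  # F, M
    probs = (
        year1[:, None, None, None]
        * sex_mult[None, :, None, None]
        * age_mult[None, None, :, None]
        * decline[None, None, None, :]
    )
    probs = np.clip(np.maximum(probs, 0.002), 0.0, 0.95)
    return SurvivalTable(band_edges, probs)


def default_tables() -> ModelTables:
    return ModelTables(
        transitions=TransitionParams(),
        survival=build_default_survival_table(),
        life=build_default_life_table(),
        utility_cost=UtilityCostTable(),
    )
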