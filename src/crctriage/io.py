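"""Structured-text configuration files.

YAML for configuration objects (population, risk models, pathway, delay,
disease prevalence, economics) and delimited CSV for the tabular inputs
(populations, life table, survival table) — everything a user needs to
replace the shipped synthetic stand-ins with real aggregate inputs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .population import MarginalSpec, PopulationConfig
from .risk import CoxRiskModel, LogisticRiskModel
from .disease import DiseasePrevalenceConfig
from .pathway import DelayModel, PathwayParams
from .economics import EconomicsConfig
from .markov import LifeTable, SurvivalTable
from .population import ConfigurationError

__all__ = [
    "load_population_config",
    "save_population_config",
    "load_risk_model",
    "save_risk_model",
    "load_pathway_params",
    "load_delay_model",
    "load_disease_config",
    "load_economics_config",
    "load_life_table",
    "load_survival_table",
]


def _read_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return data


def load_population_config(path) -> PopulationConfig:
    data = _read_yaml(path)
    marginals = tuple(
        MarginalSpec(
            variable_name=m["variable_name"],
            quantile_grid=tuple((float(p), float(v)) for p, v in m["quantile_grid"]),
            transform=m.get("transform", "identity"),
            binary=bool(m.get("binary", False)),
            lower_bound=m.get("lower_bound"),
            upper_bound=m.get("upper_bound"),
        )
        for m in data["marginals"]
    )
    return PopulationConfig(
        cohort_label=data["cohort_label"],
        marginals=marginals,
        correlation=tuple(tuple(float(v) for v in row) for row in data["correlation"]),
        recent_fbc_probability=float(data.get("recent_fbc_probability", 0.91)),
        n=int(data.get("n", 1000)),
        seed=int(data.get("seed", 0)),
    )


def save_population_config(cfg: PopulationConfig, path) -> None:
    data = {
        "cohort_label": cfg.cohort_label,
        "marginals": [
            {
                "variable_name": m.variable_name,
                "quantile_grid": [[p, v] for p, v in m.quantile_grid],
                "transform": m.transform,
                "binary": m.binary,
                "lower_bound": m.lower_bound,
                "upper_bound": m.upper_bound,
            }
            for m in cfg.marginals
        ],
        "correlation": [list(row) for row in cfg.correlation],
        "recent_fbc_probability": cfg.recent_fbc_probability,
        "n": cfg.n,
        "seed": cfg.seed,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_risk_model(path):
    """Load a Cox or logistic risk model from a `kind`-tagged YAML file."""
    data = _read_yaml(path)
    kind = data.get("kind")
    coefs = {k: float(v) for k, v in data["coefficients"].items()}
    transforms = {k: str(v) for k, v in data["transforms"].items()}
    if kind == "cox":
        return CoxRiskModel(
            coefficients=coefs,
            covariate_transforms=transforms,
            baseline_survival_at_horizon=float(data["baseline_survival_at_horizon"]),
        )
    if kind == "logistic":
        return LogisticRiskModel(
            intercept=float(data["intercept"]),
            coefficients=coefs,
            covariate_transforms=transforms,
        )
    raise ConfigurationError(f"{path}: unknown risk model kind {kind!r}")


def save_risk_model(model, path) -> None:
    if isinstance(model, CoxRiskModel):
        data = {
            "kind": "cox",
            "baseline_survival_at_horizon": model.baseline_survival_at_horizon,
        }
    elif isinstance(model, LogisticRiskModel):
        data = {"kind": "logistic", "intercept": model.intercept}
    else:
        raise TypeError(f"unsupported model type {type(model)!r}")
    data["coefficients"] = dict(model.coefficients)
    data["transforms"] = dict(model.covariate_transforms)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_pathway_params(path) -> PathwayParams:
    return PathwayParams(**_read_yaml(path))


def load_delay_model(path) -> DelayModel:
    return DelayModel(**_read_yaml(path))


def load_economics_config(path) -> EconomicsConfig:
    return EconomicsConfig(**_read_yaml(path))


def load_disease_config(path) -> DiseasePrevalenceConfig:
    data = _read_yaml(path)
    if "ibd_prevalence" in data:
        data["ibd_prevalence"] = tuple(
            (float(lo), float(hi), str(stratum), float(p))
            for lo, hi, stratum, p in data["ibd_prevalence"]
        )
    if "crc_stage_distribution" in data:
        data["crc_stage_distribution"] = tuple(float(v) for v in data["crc_stage_distribution"])
    return DiseasePrevalenceConfig(**data)


def load_life_table(path) -> LifeTable:
    return LifeTable.from_dataframe(pd.read_csv(path))


def load_survival_table(path) -> SurvivalTable:
    return SurvivalTable.from_dataframe(pd.read_csv(path))
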