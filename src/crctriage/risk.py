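"""One-year CRC risk models and threshold referral rules.

Two pluggable model forms estimate a patient's probability of a colorectal
cancer diagnosis within one year from age, sex, FIT and full-blood-count
covariates: a Cox proportional-hazards form (risk = 1 - S0^exp(lp)) and a
logistic form.  A Strategy turns either the raw FIT value or the model risk
plus a threshold into a referral decision; comparison is inclusive (>=).

Coefficients are data, not code: the shipped defaults (see
:mod:`crctriage.defaults`) are synthetic stand-ins, and real coefficient
files can be loaded via :mod:`crctriage.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .population import ConfigurationError, Person, Population

__all__ = [
    "CoxRiskModel",
    "LogisticRiskModel",
    "StrategyKind",
    "Strategy",
    "linear_predictor",
    "cox_risk",
    "logistic_risk",
    "predict_risk",
    "stratify",
    "performance_summary",
]

_TRANSFORMS = {
    "identity": lambda x: x,
    "log1p": lambda x: np.log1p(x),
}


def _apply_transform(kind: str, x):
    try:
        return _TRANSFORMS[kind](x)
    except KeyError:
        raise ConfigurationError(f"unknown covariate transform '{kind}'") from None


@dataclass(frozen=True)
class CoxRiskModel:
    """Cox-form risk model: risk(1y) = 1 - S0 ** exp(linear predictor)."""

    coefficients: dict[str, float]
    covariate_transforms: dict[str, str]
    baseline_survival_at_horizon: float

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_survival_at_horizon <= 1.0:
            raise ConfigurationError("baseline survival must be in (0, 1]")
        _check_transforms(self.coefficients, self.covariate_transforms)


@dataclass(frozen=True)
class LogisticRiskModel:
    """Logistic-form risk model: risk = expit(intercept + linear predictor)."""

    intercept: float
    coefficients: dict[str, float]
    covariate_transforms: dict[str, str]

    def __post_init__(self) -> None:
        _check_transforms(self.coefficients, self.covariate_transforms)


def _check_transforms(coefs: dict[str, float], transforms: dict[str, str]) -> None:
    missing = [c for c in coefs if c not in transforms]
    if missing:
        raise ConfigurationError(
            f"covariates without a transform entry: {missing}"
        )
    for kind in transforms.values():
        if kind not in _TRANSFORMS:
            raise ConfigurationError(f"unknown covariate transform '{kind}'")


class StrategyKind(str, Enum):
    FIT = "fit"
    COX_RISK = "cox_risk"
    LOGISTIC_RISK = "logistic_risk"
    REFER_ALL = "refer_all"


@dataclass(frozen=True)
class Strategy:
    """A referral rule: score kind + inclusive threshold.

    The threshold is in µg Hb/g faeces for ``fit`` and a risk probability
    for the model kinds; ``refer_all`` ignores it.
    """

    kind: StrategyKind
    threshold: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ConfigurationError("threshold must be >= 0")
        if self.kind in (StrategyKind.COX_RISK, StrategyKind.LOGISTIC_RISK):
            if self.threshold > 1:
                raise ConfigurationError("risk threshold must be <= 1")
        if not self.label:
            default = {
                StrategyKind.FIT: f"FIT {self.threshold:g}",
                StrategyKind.COX_RISK: f"Cox risk {100 * self.threshold:g}%",
                StrategyKind.LOGISTIC_RISK: f"Logistic risk {100 * self.threshold:g}%",
                StrategyKind.REFER_ALL: "Refer all",
            }[self.kind]
            object.__setattr__(self, "label", default)

    @property
    def uses_risk_model(self) -> bool:
        return self.kind in (StrategyKind.COX_RISK, StrategyKind.LOGISTIC_RISK)


def linear_predictor(model, subject) -> float | np.ndarray:
    """Sum of coefficient * transform(covariate); vectorised for populations."""
    if isinstance(subject, Population):
        lp = np.zeros(len(subject))
        for name, beta in model.coefficients.items():
            x = subject.covariate_column(name)
            lp += beta * _apply_transform(model.covariate_transforms[name], x)
        return lp
    if isinstance(subject, Person):
        total = 0.0
        for name, beta in model.coefficients.items():
            x = subject.covariate(name)
            total += beta * float(
                _apply_transform(model.covariate_transforms[name], x)
            )
        return total
    raise TypeError(f"unsupported subject type {type(subject)!r}")


def cox_risk(model: CoxRiskModel, subject):
    """1-year risk under the Cox form; bounded in [0, 1)."""
    lp = linear_predictor(model, subject)
    s0 = model.baseline_survival_at_horizon
    return 1.0 - np.power(s0, np.exp(lp)) if isinstance(lp, np.ndarray) else 1.0 - s0 ** math.exp(lp)


def logistic_risk(model: LogisticRiskModel, subject):
    """Risk under the logistic form; bounded in (0, 1)."""
    lp = linear_predictor(model, subject)
    z = model.intercept + lp
    if isinstance(z, np.ndarray):
        return 1.0 / (1.0 + np.exp(-z))
    return 1.0 / (1.0 + math.exp(-z))


def predict_risk(model, subject):
    """Dispatch on model form."""
    if isinstance(model, CoxRiskModel):
        return cox_risk(model, subject)
    if isinstance(model, LogisticRiskModel):
        return logistic_risk(model, subject)
    raise TypeError(f"unsupported risk model type {type(model)!r}")


def stratify(pop: Population, strategy: Strategy, risk_model=None) -> np.ndarray:
    """Per-person boolean referral indicator under a strategy.

    Patients with score (FIT value or model risk) greater than or equal to
    the threshold are referred on the urgent suspected-cancer pathway.
    """
    if strategy.kind is StrategyKind.REFER_ALL:
        return np.ones(len(pop), dtype=bool)
    if strategy.kind is StrategyKind.FIT:
        return pop.df["fit"].to_numpy(dtype=float) >= strategy.threshold
    if risk_model is None:
        raise ConfigurationError(
            f"strategy '{strategy.label}' needs a risk model"
        )
    risks = np.asarray(predict_risk(risk_model, pop))
    return risks >= strategy.threshold


def performance_summary(
    pop: Population, strategy: Strategy, true_crc_flags, risk_model=None
) -> dict[str, float]:
    """Referral counts and classification performance against true CRC status.

    sensitivity = referred CRC / all CRC; specificity = unreferred non-CRC /
    all non-CRC; PPV = referred CRC / referred.  NaN where a denominator is
    empty.
    """
    flags = np.asarray(true_crc_flags, dtype=bool)
    if flags.shape[0] != len(pop):
        raise ValueError(
            f"true_crc_flags length {flags.shape[0]} != population size {len(pop)}"
        )
    referred = stratify(pop, strategy, risk_model)
    tp = int(np.sum(referred & flags))
    n_crc = int(flags.sum())
    n_ref = int(referred.sum())
    n_neg = int((~flags).sum())
    tn = int(np.sum(~referred & ~flags))
    return {
        "referrals": n_ref,
        "crc_detected_if_referred": tp,
        "sensitivity": tp / n_crc if n_crc else float("nan"),
        "specificity": tn / n_neg if n_neg else float("nan"),
        "ppv": tp / n_ref if n_ref else float("nan"),
    }
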