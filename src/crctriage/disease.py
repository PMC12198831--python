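"""Baseline disease allocation.

Each synthetic patient receives one mutually exclusive colorectal state —
CRC (stage I–IV), high-risk adenoma, low-risk adenoma or normal epithelium —
plus an independent inflammatory-bowel-disease flag.

CRC is applied randomly with per-person probability equal to the modelled
1-year risk, reproducing the cohort's incidence.  High-risk adenomas sit at
different prevalences in the FIT>=10 and FIT<10 strata and are weighted
within stratum by risk score (the score has some sensitivity for them);
low-risk adenomas are uniform.  IBD prevalence varies by age band and FIT
stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import ConfigurationError, Population

__all__ = [
    "DiseasePrevalenceConfig",
    "BaselineState",
    "BaselineStates",
    "CRC_STAGES",
    "allocate_crc",
    "allocate_adenomas",
    "allocate_ibd",
    "allocate_baseline_states",
    "calibrate_prevalence_scaling",
]

CRC_STAGES = ("I", "II", "III", "IV")
STAGE_NONE = "none"
ADENOMA_STATES = ("none", "low_risk", "high_risk")


@dataclass(frozen=True)
class DiseasePrevalenceConfig:
    """Baseline prevalence inputs.

    ``ibd_prevalence`` maps ``(age_lo, age_hi, fit_stratum)`` bands to a
    probability, where ``fit_stratum`` is ``"lt10"`` or ``"ge10"`` and the
    band covers ages in [age_lo, age_hi).  ``prevalence_scaling`` multiplies
    each person's CRC risk before the Bernoulli draw (default 1: risks are
    already calibrated).
    """

    crc_stage_distribution: tuple[float, float, float, float] = (
        0.25,
        0.30,
        0.30,
        0.15,
    )
    hr_adenoma_prevalence: dict[str, float] = field(
        default_factory=lambda: {"ge10": 0.08, "lt10": 0.015}
    )
    lr_adenoma_prevalence: float = 0.10
    ibd_prevalence: tuple[tuple[float, float, str, float], ...] = ()
    prevalence_scaling: float = 1.0

    def __post_init__(self) -> None:
        dist = np.asarray(self.crc_stage_distribution, dtype=float)
        if dist.shape != (4,):
            raise ConfigurationError("stage distribution needs 4 entries (I-IV)")
        if np.any(dist < 0) or abs(dist.sum() - 1.0) > 1e-9:
            raise ConfigurationError("stage distribution must be probabilities summing to 1")
        for key in ("ge10", "lt10"):
            p = self.hr_adenoma_prevalence.get(key)
            if p is None or not 0 <= p <= 1:
                raise ConfigurationError(
                    f"hr_adenoma_prevalence['{key}'] must be in [0, 1]"
                )
        if not 0 <= self.lr_adenoma_prevalence <= 1:
            raise ConfigurationError("lr_adenoma_prevalence outside [0, 1]")
        for lo, hi, stratum, p in self.ibd_prevalence:
            if stratum not in ("lt10", "ge10") or not 0 <= p <= 1 or hi <= lo:
                raise ConfigurationError(f"bad IBD band {(lo, hi, stratum, p)}")
        if self.prevalence_scaling < 0:
            raise ConfigurationError("prevalence_scaling must be >= 0")


@dataclass(frozen=True)
class BaselineState:
    """One person's underlying truth at baseline."""

    person_id: int
    crc_stage: str  # "none" or "I".."IV"
    adenoma: str  # "none", "low_risk", "high_risk"
    ibd: bool

    def __post_init__(self) -> None:
        if self.crc_stage not in (STAGE_NONE, *CRC_STAGES):
            raise ValueError(f"bad crc_stage {self.crc_stage!r}")
        if self.adenoma not in ADENOMA_STATES:
            raise ValueError(f"bad adenoma state {self.adenoma!r}")
        if self.crc_stage != STAGE_NONE and self.adenoma != "none":
            raise ValueError("CRC and adenoma states are mutually exclusive")


class BaselineStates:
    """Vectorised container of per-person baseline states (order = population)."""

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def crc_stage(self) -> np.ndarray:
        return self.df["crc_stage"].to_numpy()

    @property
    def adenoma(self) -> np.ndarray:
        return self.df["adenoma"].to_numpy()

    @property
    def ibd(self) -> np.ndarray:
        return self.df["ibd"].to_numpy(dtype=bool)

    @property
    def has_crc(self) -> np.ndarray:
        return self.crc_stage != STAGE_NONE

    def records(self) -> list[BaselineState]:
        return [
            BaselineState(int(r.person_id), r.crc_stage, r.adenoma, bool(r.ibd))
            for r in self.df.itertuples(index=False)
        ]


def _fit_stratum(fit: np.ndarray) -> np.ndarray:
    return np.where(fit >= 10.0, "ge10", "lt10")


def allocate_crc(
    pop: Population,
    risks,
    cfg: DiseasePrevalenceConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-person CRC stage ("none" or I-IV) from individual 1-year risk.

    CRC occurs with probability ``prevalence_scaling * risk`` (capped at 1,
    with a warning counting capped persons); the stage of a case is drawn
    independently from the configured baseline stage distribution.
    """
    risks = np.asarray(risks, dtype=float)
    if risks.shape[0] != len(pop):
        raise ValueError("risks length != population size")
    if np.any((risks < 0) | (risks > 1)):
        raise ValueError("risks must lie in [0, 1]")
    p = cfg.prevalence_scaling * risks
    n_capped = int(np.sum(p > 1.0))
    if n_capped:
        warnings.warn(
            f"{n_capped} person(s) had scaled CRC risk > 1; capped at 1",
            stacklevel=2,
        )
        p = np.minimum(p, 1.0)
    has_crc = rng.random(len(pop)) < p
    stages = np.full(len(pop), STAGE_NONE, dtype=object)
    n_cases = int(has_crc.sum())
    if n_cases:
        stage_idx = rng.choice(4, size=n_cases, p=np.asarray(cfg.crc_stage_distribution))
        stages[has_crc] = np.asarray(CRC_STAGES, dtype=object)[stage_idx]
    return stages


def allocate_adenomas(
    pop: Population,
    risk_scores,
    crc_stages: np.ndarray,
    cfg: DiseasePrevalenceConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Adenoma state among CRC-free persons.

    High-risk adenoma probability within each FIT stratum is proportional to
    the person's risk score, rescaled so the stratum mean equals the stratum
    prevalence (capped at 1).  Low-risk adenomas are then allocated
    uniformly among the remainder.
    """
    scores = np.asarray(risk_scores, dtype=float)
    out = np.full(len(pop), "none", dtype=object)
    crc_free = crc_stages == STAGE_NONE
    fit = pop.df["fit"].to_numpy(dtype=float)
    strata = _fit_stratum(fit)
    u_hr = rng.random(len(pop))
    u_lr = rng.random(len(pop))
    hr = np.zeros(len(pop), dtype=bool)
    for key in ("ge10", "lt10"):
        mask = crc_free & (strata == key)
        if not mask.any():
            continue
        prev = cfg.hr_adenoma_prevalence[key]
        s = scores[mask]
        mean_s = s.mean()
        if prev == 0.0:
            probs = np.zeros(mask.sum())
        elif mean_s <= 0:
            probs = np.full(mask.sum(), prev)
        else:
            probs = np.minimum(prev * s / mean_s, 1.0)
        hr[mask] = u_hr[mask] < probs
    out[hr] = "high_risk"
    lr_pool = crc_free & ~hr
    out[lr_pool & (u_lr < cfg.lr_adenoma_prevalence)] = "low_risk"
    return out


def allocate_ibd(
    pop: Population,
    cfg: DiseasePrevalenceConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent IBD flag from the (age band x FIT stratum) prevalence table."""
    age = pop.df["age"].to_numpy(dtype=float)
    fit = pop.df["fit"].to_numpy(dtype=float)
    strata = _fit_stratum(fit)
    p = np.full(len(pop), np.nan)
    for lo, hi, stratum, rate in cfg.ibd_prevalence:
        mask = (age >= lo) & (age < hi) & (strata == stratum)
        p[mask] = rate
    if np.isnan(p).any():
        bad = np.where(np.isnan(p))[0][0]
        raise ConfigurationError(
            f"IBD prevalence table does not cover age={age[bad]:.1f}, "
            f"FIT stratum={strata[bad]}"
        )
    return rng.random(len(pop)) < p


def allocate_baseline_states(
    pop: Population,
    risks,
    cfg: DiseasePrevalenceConfig,
    rng: np.random.Generator,
) -> BaselineStates:
    """Full baseline allocation: CRC, then adenomas among CRC-free, then IBD."""
    crc = allocate_crc(pop, risks, cfg, rng)
    adenoma = allocate_adenomas(pop, risks, crc, cfg, rng)
    if cfg.ibd_prevalence:
        ibd = allocate_ibd(pop, cfg, rng)
    else:
        ibd = np.zeros(len(pop), dtype=bool)
    return BaselineStates(
        pd.DataFrame(
            {
                "person_id": pop.df["id"].to_numpy(),
                "crc_stage": crc,
                "adenoma": adenoma,
                "ibd": ibd,
            }
        )
    )


def calibrate_prevalence_scaling(risks, target_prevalence: float) -> float:
    """Multiplier making the mean scaled risk equal a target prevalence."""
    risks = np.asarray(risks, dtype=float)
    mean = risks.mean()
    if mean <= 0:
        raise ConfigurationError("cannot calibrate: mean risk is zero")
    return float(target_prevalence / mean)
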