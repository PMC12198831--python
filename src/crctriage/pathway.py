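"""Short-term diagnostic model.

Simulates, for one referral strategy, what happens between the GP visit and
definitive diagnosis: urgent-referral uptake, colonoscopy or CT colonography
(CTC), per-condition detection or miss, a personalised diagnostic delay for
missed/unreferred disease, emergency presentation in a share of delayed CRC
cases, and all short-term costs and investigation harms.

Strategy comparisons are paired through common random numbers: each person
carries a fixed vector of uniform draws (uptake, CTC assignment, detection
per condition, delay, emergency) generated once per population and reused by
every strategy, so a person whose referral status agrees under two
strategies gets identical outcomes under both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .population import ConfigurationError, Population
from .risk import Strategy
from .disease import BaselineStates

__all__ = [
    "PathwayParams",
    "DelayModel",
    "ScenarioFlags",
    "PathwayDraws",
    "DiagnosticOutcome",
    "DiagnosticOutcomes",
    "draw_pathway_uniforms",
    "sample_delay",
    "delay_quantile",
    "investigation_assignment",
    "colonoscopy_harm_qaly",
    "run_pathway",
]

CONDITIONS = ("crc", "hr_adenoma", "lr_adenoma", "ibd")


@dataclass(frozen=True)
class ScenarioFlags:
    """Behaviour toggles shared by the short- and long-term models."""

    label: str = "base"
    include_adenomas: bool = False
    include_ibd: bool = False
    colonoscopy_harm_full_day: bool = False
    fast_transitions: bool = False


@dataclass(frozen=True)
class PathwayParams:
    """Unit costs (GBP 2023), probabilities and sensitivities.

    Cost defaults other than the blood count (8.38) and the algorithm
    running cost (0.01) are synthetic stand-ins for NHS reference costs.
    ``fbc_charge_fraction`` is the share of patients charged a blood count
    under a risk-score strategy; at the default 0.09 the per-person
    ``has_recent_fbc`` flag decides who pays, while 1.0 charges everyone.
    Investigation complications (probability x QALY decrement and cost)
    apply to colonoscopy only.
    """

    uptake_probability: float = 0.95
    colonoscopy_sensitivity: dict[str, float] = field(
        default_factory=lambda: {
            "crc": 0.95,
            "hr_adenoma": 0.90,
            "lr_adenoma": 0.75,
            "ibd": 0.90,
        }
    )
    ctc_fraction: float = 0.15
    ctc_sensitivity: dict[str, float] = field(
        default_factory=lambda: {
            "crc": 0.90,
            "hr_adenoma": 0.60,
            "lr_adenoma": 0.30,
            "ibd": 0.20,
        }
    )
    cost_gp_appointment: float = 42.0
    cost_fit: float = 5.0
    cost_fbc: float = 8.38
    cost_algorithm: float = 0.01
    cost_colonoscopy: float = 650.0
    cost_ctc: float = 220.0
    cost_extra_gp: float = 42.0
    cost_emergency: float = 3700.0
    emergency_fraction_delayed: float = 0.20
    extra_gp_appointments_delayed: float = 2.0
    complication_probability: float = 0.0005
    complication_qaly_decrement: float = 0.05
    complication_cost: float = 1500.0
    fbc_charge_fraction: float = 0.09

    def __post_init__(self) -> None:
        for name in (
            "uptake_probability",
            "ctc_fraction",
            "emergency_fraction_delayed",
            "complication_probability",
            "fbc_charge_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in (
            "cost_gp_appointment",
            "cost_fit",
            "cost_fbc",
            "cost_algorithm",
            "cost_colonoscopy",
            "cost_ctc",
            "cost_extra_gp",
            "cost_emergency",
            "complication_cost",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for table_name in ("colonoscopy_sensitivity", "ctc_sensitivity"):
            table = getattr(self, table_name)
            for cond in CONDITIONS:
                p = table.get(cond)
                if p is None or not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"{table_name}['{cond}'] must be in [0, 1]"
                    )


@dataclass(frozen=True)
class DelayModel:
    """Personalised diagnostic delay for CRC missed by the urgent pathway.

    Truncated lognormal on [min, max] years with log-scale spread ``sigma``;
    the location parameter is solved numerically so the truncated mean
    equals ``mean``.  Defaults: mean 3 months, range 2 weeks to 2 years.
    IBD missed at referral waits a fixed ``ibd_delay`` years.
    """

    mean: float = 0.25
    min: float = 2.0 / 52.0
    max: float = 2.0
    sigma: float = 0.8
    family: str = "truncated-lognormal"
    ibd_delay: float = 1.34

    def __post_init__(self) -> None:
        degenerate = self.min == self.max == self.mean
        if not degenerate and not self.min < self.mean < self.max:
            raise ConfigurationError(
                f"delay mean {self.mean} outside (min={self.min}, max={self.max})"
            )
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        if self.family != "truncated-lognormal":
            raise ConfigurationError(f"unknown delay family '{self.family}'")


@lru_cache(maxsize=32)
def _solve_delay_mu(mean: float, lo: float, hi: float, sigma: float) -> float:
    """Location mu such that the [lo, hi]-truncated lognormal mean is `mean`."""
    la, lb = np.log(lo), np.log(hi)

    def truncated_mean(mu: float) -> float:
        a = (la - mu) / sigma
        b = (lb - mu) / sigma
        mass = stats.norm.cdf(b) - stats.norm.cdf(a)
        if mass <= 0:
            return lo if mu < la else hi
        shifted = stats.norm.cdf(b - sigma) - stats.norm.cdf(a - sigma)
        return float(np.exp(mu + 0.5 * sigma**2) * shifted / mass)

    # truncated mean is increasing in mu and spans (lo, hi)
    return float(
        optimize.brentq(lambda m: truncated_mean(m) - mean, la - 10, lb + 10)
    )


def delay_quantile(model: DelayModel, u) -> np.ndarray:
    """Inverse CDF of the truncated-lognormal delay; the CRN entry point."""
    if model.min == model.max:
        return np.full(np.shape(u), model.min)
    mu = _solve_delay_mu(model.mean, model.min, model.max, model.sigma)
    la = (np.log(model.min) - mu) / model.sigma
    lb = (np.log(model.max) - mu) / model.sigma
    ca, cb = stats.norm.cdf(la), stats.norm.cdf(lb)
    z = stats.norm.ppf(ca + np.asarray(u) * (cb - ca))
    return np.clip(np.exp(mu + model.sigma * z), model.min, model.max)


def sample_delay(model: DelayModel, rng: np.random.Generator, size=None):
    """Draw diagnostic delays in years; all draws lie in [min, max]."""
    if model.min == model.max:
        return np.full(size or 1, model.min) if size else model.min
    u = rng.random(size if size is not None else 1)
    out = delay_quantile(model, u)
    return out if size is not None else float(out[0])


def investigation_assignment(params: PathwayParams, rng: np.random.Generator, size=None):
    """CTC with probability ctc_fraction, else colonoscopy."""
    u = rng.random(size if size is not None else 1)
    out = np.where(u < params.ctc_fraction, "ctc", "colonoscopy")
    return out if size is not None else str(out[0])


def colonoscopy_harm_qaly(scenario: ScenarioFlags, params: PathwayParams) -> float:
    """QALY loss per colonoscopy.

    The full-day-of-health scenario charges exactly one day (1/365.25 QALY)
    per procedure; otherwise the base case charges the expected complication
    decrement (probability x decrement).
    """
    if scenario.colonoscopy_harm_full_day:
        return 1.0 / 365.25
    return params.complication_probability * params.complication_qaly_decrement


@dataclass(frozen=True)
class PathwayDraws:
    """Per-person uniforms shared across strategies (common random numbers)."""

    uptake: np.ndarray
    ctc: np.ndarray
    detect_crc: np.ndarray
    detect_adenoma: np.ndarray
    detect_ibd: np.ndarray
    delay: np.ndarray
    emergency: np.ndarray

    def __len__(self) -> int:
        return len(self.uptake)


def draw_pathway_uniforms(n: int, rng: np.random.Generator) -> PathwayDraws:
    return PathwayDraws(*(rng.random(n) for _ in range(7)))


@dataclass(frozen=True)
class DiagnosticOutcome:
    """Per-person short-term result."""

    person_id: int
    referred: bool
    attended: bool
    investigation: str  # "colonoscopy", "ctc", "none"
    crc_detected_usc: bool
    crc_diagnosis_delay: float
    adenoma_detected: bool
    ibd_detected_usc: bool
    ibd_diagnosis_delay: float
    short_term_cost: float
    short_term_qaly_loss: float
    delayed_dx_cost: float = 0.0


class DiagnosticOutcomes:
    """Vectorised short-term results, one row per person (population order).

    ``short_term_cost`` holds year-0 costs; ``delayed_dx_cost`` holds the
    costs incurred at a delayed CRC diagnosis (investigation, extra GP
    visits, emergency presentation), discounted downstream by the delay.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> list[DiagnosticOutcome]:
        return [
            DiagnosticOutcome(
                int(r.person_id),
                bool(r.referred),
                bool(r.attended),
                str(r.investigation),
                bool(r.crc_detected_usc),
                float(r.crc_diagnosis_delay),
                bool(r.adenoma_detected),
                bool(r.ibd_detected_usc),
                float(r.ibd_diagnosis_delay),
                float(r.short_term_cost),
                float(r.short_term_qaly_loss),
                float(r.delayed_dx_cost),
            )
            for r in self.df.itertuples(index=False)
        ]


def run_pathway(
    pop: Population,
    baseline_states: BaselineStates,
    referrals,
    strategy: Strategy,
    params: PathwayParams,
    delay_model: DelayModel,
    scenario: ScenarioFlags = ScenarioFlags(),
    rng: np.random.Generator | None = None,
    draws: PathwayDraws | None = None,
) -> DiagnosticOutcomes:
    """Run the short-term model for one strategy.

    Pass ``draws`` (from :func:`draw_pathway_uniforms`) to pair strategies
    on common random numbers; otherwise fresh uniforms are drawn from
    ``rng``.
    """
    n = len(pop)
    referrals = np.asarray(referrals, dtype=bool)
    if referrals.shape[0] != n or len(baseline_states) != n:
        raise ValueError("population, baseline states and referrals must align")
    if draws is None:
        if rng is None:
            raise ValueError("provide either rng or draws")
        draws = draw_pathway_uniforms(n, rng)
    if len(draws) != n:
        raise ValueError("draws length != population size")

    has_crc = baseline_states.has_crc
    adenoma = baseline_states.adenoma
    has_ibd = baseline_states.ibd

    attended = referrals & (draws.uptake < params.uptake_probability)
    is_ctc = draws.ctc < params.ctc_fraction
    investigation = np.where(attended, np.where(is_ctc, "ctc", "colonoscopy"), "none")

    def sens_for(condition: str) -> np.ndarray:
        return np.where(
            is_ctc,
            params.ctc_sensitivity[condition],
            params.colonoscopy_sensitivity[condition],
        )

    crc_detected = attended & has_crc & (draws.detect_crc < sens_for("crc"))
    adenoma_cond = np.where(adenoma == "high_risk", "hr_adenoma", "lr_adenoma")
    adenoma_sens = np.where(
        adenoma_cond == "hr_adenoma", sens_for("hr_adenoma"), sens_for("lr_adenoma")
    )
    adenoma_detected = attended & (adenoma != "none") & (draws.detect_adenoma < adenoma_sens)
    ibd_found = attended & has_ibd & (draws.detect_ibd < sens_for("ibd"))
    ibd_detected = ibd_found & scenario.include_ibd

    delays = np.zeros(n)
    crc_delayed = has_crc & ~crc_detected
    delays[crc_delayed] = delay_quantile(delay_model, draws.delay[crc_delayed])

    ibd_delays = np.zeros(n)
    ibd_delays[has_ibd & ~ibd_detected] = delay_model.ibd_delay

    # --- year-0 costs ---
    cost = np.full(n, params.cost_gp_appointment + params.cost_fit)
    if strategy.uses_risk_model:
        cost += params.cost_algorithm
        if params.fbc_charge_fraction >= 1.0:
            charged_fbc = np.ones(n, dtype=bool)
        else:
            charged_fbc = ~pop.df["has_recent_fbc"].to_numpy(dtype=bool)
        cost += np.where(charged_fbc, params.cost_fbc, 0.0)
    inv_cost = np.where(is_ctc, params.cost_ctc, params.cost_colonoscopy)
    cost += np.where(attended, inv_cost, 0.0)
    colonoscopy_done = attended & ~is_ctc
    cost += np.where(colonoscopy_done, params.complication_probability * params.complication_cost, 0.0)

    # --- costs at delayed CRC diagnosis (incurred `delay` years later) ---
    delayed_cost = np.zeros(n)
    delayed_cost[crc_delayed] = (
        params.cost_colonoscopy
        + params.extra_gp_appointments_delayed * params.cost_extra_gp
    )
    emergency = crc_delayed & (draws.emergency < params.emergency_fraction_delayed)
    delayed_cost[emergency] += params.cost_emergency

    harm = colonoscopy_harm_qaly(scenario, params)
    qaly_loss = np.where(colonoscopy_done, harm, 0.0)

    df = pd.DataFrame(
        {
            "person_id": pop.df["id"].to_numpy(),
            "referred": referrals,
            "attended": attended,
            "investigation": investigation,
            "crc_detected_usc": crc_detected,
            "crc_diagnosis_delay": delays,
            "adenoma_detected": adenoma_detected,
            "ibd_detected_usc": ibd_detected,
            "ibd_diagnosis_delay": ibd_delays,
            "short_term_cost": cost,
            "short_term_qaly_loss": qaly_loss,
            "delayed_dx_cost": delayed_cost,
        }
    )
    return DiagnosticOutcomes(df)
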