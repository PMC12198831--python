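"""Aggregation and cost-effectiveness arithmetic.

Person-level short-term and lifetime results are summed into per-million
strategy outcomes; pairwise incrementals carry the incremental net monetary
benefit INMB = lambda * dQALY - dCost at a willingness to pay of
20,000 GBP/QALY by default.  ICERs are reported but flagged when the signs
of dCost and dQALY make a ratio misleading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import Population
from .markov import LifeCourseResults, discount
from .pathway import DiagnosticOutcomes

__all__ = [
    "EconomicsConfig",
    "StrategyOutcome",
    "IncrementalResult",
    "SubgroupSpec",
    "aggregate",
    "inmb",
    "incremental",
    "subgroup_outcomes",
    "qaly_loss_per_delayed_diagnosis",
]


@dataclass(frozen=True)
class EconomicsConfig:
    """Willingness to pay, discounting and reporting scale (GBP 2023)."""

    wtp: float = 20000.0
    discount_rate: float = 0.035
    scale: float = 1_000_000.0
    currency_year: int = 2023

    def __post_init__(self) -> None:
        if self.wtp < 0 or self.discount_rate < 0 or self.scale <= 0:
            raise ValueError("wtp and discount rate must be >= 0; scale > 0")


@dataclass(frozen=True)
class StrategyOutcome:
    """Totals per ``scale`` persons for one strategy."""

    label: str
    cost: float
    qaly: float
    ly: float
    crc_deaths: float
    usc_referrals: float
    usc_crc_diagnoses: float
    scale: float = 1_000_000.0
    n_simulated: int = 0

    def __post_init__(self) -> None:
        if self.usc_crc_diagnoses > self.usc_referrals + 1e-9:
            raise ValueError("USC CRC diagnoses cannot exceed USC referrals")


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise comparison A minus B, with INMB = wtp * dQ - dC."""

    label_a: str
    label_b: str
    d_cost: float
    d_qaly: float
    d_ly: float
    d_crc_deaths: float
    d_referrals: float
    d_usc_diagnoses: float
    inmb: float
    icer: float = float("nan")
    icer_flagged: bool = False


@dataclass(frozen=True)
class SubgroupSpec:
    """Age-band x sex partition; bands are [lo, hi) on the configured range."""

    age_edges: tuple[float, ...] = (18.0, 50.0, 70.0, 101.0)
    sexes: tuple[str, ...] = ("F", "M")

    def band_labels(self) -> list[str]:
        out = []
        for lo, hi in zip(self.age_edges[:-1], self.age_edges[1:]):
            out.append(f"{lo:g}-{hi:g}")
        return out


def aggregate(
    lifecourse: LifeCourseResults,
    diag: DiagnosticOutcomes,
    cfg: EconomicsConfig,
    label: str = "",
    mask: np.ndarray | None = None,
    rescale: bool = True,
) -> StrategyOutcome:
    """Sum person-level results into a per-``scale`` strategy outcome.

    Short-term costs accrue in year 0 (undiscounted); costs incurred at a
    delayed CRC diagnosis are discounted by the personal delay.  Short-term
    investigation harms are subtracted from lifetime QALYs.
    """
    n_total = len(lifecourse)
    if n_total == 0:
        raise ValueError("cannot aggregate an empty cohort")
    if len(diag) != n_total:
        raise ValueError("lifecourse and diagnostic outcomes must align")
    lf = lifecourse.df
    dg = diag.df
    if mask is None:
        mask = np.ones(n_total, dtype=bool)

    delayed_cost_disc = discount(
        dg["delayed_dx_cost"].to_numpy(),
        dg["crc_diagnosis_delay"].to_numpy(),
        cfg.discount_rate,
    )
    cost = (
        lf["discounted_cost"].to_numpy()
        + dg["short_term_cost"].to_numpy()
        + np.asarray(delayed_cost_disc)
    )[mask].sum()
    qaly = (
        lf["discounted_qaly"].to_numpy() - dg["short_term_qaly_loss"].to_numpy()
    )[mask].sum()
    ly = lf["discounted_ly"].to_numpy()[mask].sum()
    deaths = lf["crc_death_probability"].to_numpy()[mask].sum()
    referrals = dg["referred"].to_numpy(dtype=bool)[mask].sum()
    usc_dx = dg["crc_detected_usc"].to_numpy(dtype=bool)[mask].sum()

    mult = cfg.scale / n_total if rescale else 1.0
    return StrategyOutcome(
        label=label,
        cost=float(cost * mult),
        qaly=float(qaly * mult),
        ly=float(ly * mult),
        crc_deaths=float(deaths * mult),
        usc_referrals=float(referrals * mult),
        usc_crc_diagnoses=float(usc_dx * mult),
        scale=cfg.scale if rescale else float(n_total),
        n_simulated=int(mask.sum()),
    )


def inmb(d_cost: float, d_qaly: float, wtp: float) -> float:
    """Incremental net monetary benefit: wtp * dQALY - dCost."""
    return wtp * d_qaly - d_cost


def incremental(
    a: StrategyOutcome, b: StrategyOutcome, cfg: EconomicsConfig
) -> IncrementalResult:
    """Component-wise A - B with INMB; antisymmetric in its arguments."""
    if a.scale != b.scale:
        raise ValueError(f"scale mismatch: {a.scale} vs {b.scale}")
    d_cost = a.cost - b.cost
    d_qaly = a.qaly - b.qaly
    icer = d_cost / d_qaly if d_qaly != 0 else float("nan")
    # an ICER is misleading when one quadrant dominates (signs differ from
    # the NE/SW trade-off quadrants)
    flagged = (d_cost <= 0 and d_qaly >= 0) or (d_cost >= 0 and d_qaly <= 0)
    return IncrementalResult(
        label_a=a.label,
        label_b=b.label,
        d_cost=d_cost,
        d_qaly=d_qaly,
        d_ly=a.ly - b.ly,
        d_crc_deaths=a.crc_deaths - b.crc_deaths,
        d_referrals=a.usc_referrals - b.usc_referrals,
        d_usc_diagnoses=a.usc_crc_diagnoses - b.usc_crc_diagnoses,
        inmb=inmb(d_cost, d_qaly, cfg.wtp),
        icer=icer,
        icer_flagged=flagged,
    )


def subgroup_outcomes(
    pop: Population,
    lifecourse: LifeCourseResults,
    diag: DiagnosticOutcomes,
    spec: SubgroupSpec,
    cfg: EconomicsConfig,
    label: str = "",
) -> dict[tuple[str, str], StrategyOutcome]:
    """Unscaled outcomes per (age band, sex) cell; cells sum to the whole.

    Raises if any person falls outside the band partition.
    """
    age = pop.df["age"].to_numpy(dtype=float)
    sex = pop.df["sex"].to_numpy()
    covered = np.zeros(len(pop), dtype=bool)
    out: dict[tuple[str, str], StrategyOutcome] = {}
    for lo, hi, band in zip(
        spec.age_edges[:-1], spec.age_edges[1:], spec.band_labels()
    ):
        for sx in spec.sexes:
            mask = (age >= lo) & (age < hi) & (sex == sx)
            covered |= mask
            if not mask.any():
                continue
            out[(band, sx)] = aggregate(
                lifecourse, diag, cfg, label=f"{label}[{band},{sx}]", mask=mask, rescale=False
            )
    if not covered.all():
        i = int(np.where(~covered)[0][0])
        raise ValueError(
            f"person id {pop.df['id'].iloc[i]} (age {age[i]:.1f}, sex {sex[i]}) "
            "falls outside the subgroup partition"
        )
    return out


def qaly_loss_per_delayed_diagnosis(
    immediate: LifeCourseResults,
    delayed: LifeCourseResults,
    case_mask: np.ndarray,
) -> float:
    """Mean discounted QALY(immediate dx) - QALY(delayed dx) over CRC cases.

    ``immediate`` and ``delayed`` must be paired person-for-person runs of
    the lifetime model differing only in the diagnostic delay; ``case_mask``
    selects the CRC cases in the band of interest.
    """
    mask = np.asarray(case_mask, dtype=bool)
    if not mask.any():
        raise ValueError("no CRC cases in the requested band")
    qi = immediate.df["discounted_qaly"].to_numpy()[mask]
    qd = delayed.df["discounted_qaly"].to_numpy()[mask]
    return float(np.mean(qi - qd))
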