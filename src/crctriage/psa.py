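"""Probabilistic sensitivity analysis.

Each PSA run draws one parameter set from the configured uncertainty
distributions (beta for probabilities and utilities, gamma for costs,
lognormal for transition/hazard-type parameters), generates a fresh cohort
from a run-indexed seed, evaluates every strategy on that cohort with
common random numbers, and records per-strategy outcomes.  Summaries:
probability cost-effective, cost-effectiveness acceptability curves and
empirical credible intervals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import ConfigurationError
from .risk import Strategy
from .economics import EconomicsConfig
from .pipeline import ModelBundle, evaluate_strategies

__all__ = [
    "ParameterDistribution",
    "PSAConfig",
    "PSAResult",
    "set_by_path",
    "sample_parameters",
    "default_psa_distributions",
    "run_psa",
    "probability_cost_effective",
    "ceac",
    "credible_interval",
]


@dataclass(frozen=True)
class ParameterDistribution:
    """Uncertainty on one parameter, addressed by a dot-path into the bundle.

    Families: ``beta(alpha, beta)``, ``gamma(shape, scale)``,
    ``lognormal(mu, sigma)`` (log-scale parameters), ``fixed(value)``.
    Optional truncation bounds clip the draw.
    """

    path: str
    family: str
    params: tuple[float, ...]
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        need = {"beta": 2, "gamma": 2, "lognormal": 2, "fixed": 1}
        if self.family not in need:
            raise ConfigurationError(f"unknown distribution family '{self.family}'")
        if len(self.params) != need[self.family]:
            raise ConfigurationError(
                f"{self.family} needs {need[self.family]} hyperparameter(s)"
            )
        if self.family in ("beta", "gamma") and any(p <= 0 for p in self.params):
            raise ConfigurationError(f"{self.family} hyperparameters must be positive")
        if self.family == "lognormal" and self.params[1] <= 0:
            raise ConfigurationError("lognormal sigma must be positive")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            x = self.params[0]
        elif self.family == "beta":
            x = rng.beta(*self.params)
        elif self.family == "gamma":
            x = rng.gamma(self.params[0], self.params[1])
        else:
            x = rng.lognormal(self.params[0], self.params[1])
        if self.lower is not None:
            x = max(x, self.lower)
        if self.upper is not None:
            x = min(x, self.upper)
        return float(x)


def _set_on(obj, segments: list[str], value):
    head = segments[0]
    if len(segments) == 1:
        if dataclasses.is_dataclass(obj):
            return dataclasses.replace(obj, **{head: value})
        if isinstance(obj, dict):
            new = dict(obj)
            new[head] = value
            return new
        if isinstance(obj, tuple):
            new = list(obj)
            new[int(head)] = value
            return tuple(new)
        raise TypeError(f"cannot set '{head}' on {type(obj)!r}")
    if dataclasses.is_dataclass(obj):
        child = getattr(obj, head)
        return dataclasses.replace(obj, **{head: _set_on(child, segments[1:], value)})
    if isinstance(obj, dict):
        new = dict(obj)
        new[head] = _set_on(obj[head], segments[1:], value)
        return new
    if isinstance(obj, tuple):
        i = int(head)
        new = list(obj)
        new[i] = _set_on(new[i], segments[1:], value)
        return tuple(new)
    raise TypeError(f"cannot traverse '{head}' on {type(obj)!r}")


def set_by_path(bundle: ModelBundle, path: str, value) -> ModelBundle:
    """Immutable update of a nested bundle field, e.g.
    ``pathway.cost_colonoscopy`` or ``tables.transitions.stage_progression.0``."""
    return _set_on(bundle, path.split("."), value)


def sample_parameters(
    dists: list[ParameterDistribution], rng: np.random.Generator
) -> dict[str, float]:
    """One independent draw per distribution, keyed by parameter path."""
    return {d.path: d.sample(rng) for d in dists}


def apply_parameters(bundle: ModelBundle, values: dict[str, float]) -> ModelBundle:
    for path, v in values.items():
        bundle = set_by_path(bundle, path, v)
    return bundle


def default_psa_distributions() -> list[ParameterDistribution]:
    """Moderate uncertainty on pathway probabilities, costs, utilities and
    stage transitions; population aggregates are not varied."""
    def beta_mean(mean, n=100):
        return (mean * n, (1 - mean) * n)

    def gamma_mean(mean, cv=0.2):
        shape = 1.0 / cv**2
        return (shape, mean / shape)

    return [
        ParameterDistribution("pathway.uptake_probability", "beta", beta_mean(0.95, 200)),
        ParameterDistribution("pathway.colonoscopy_sensitivity.crc", "beta", beta_mean(0.95, 200)),
        ParameterDistribution("pathway.ctc_sensitivity.crc", "beta", beta_mean(0.90, 100)),
        ParameterDistribution("pathway.cost_colonoscopy", "gamma", gamma_mean(650.0)),
        ParameterDistribution("pathway.cost_ctc", "gamma", gamma_mean(220.0)),
        ParameterDistribution("pathway.cost_emergency", "gamma", gamma_mean(3700.0)),
        ParameterDistribution("pathway.emergency_fraction_delayed", "beta", beta_mean(0.20, 100)),
        ParameterDistribution(
            "tables.transitions.stage_progression.0",
            "lognormal",
            (float(np.log(0.35)), 0.15),
            upper=0.69,
        ),
        ParameterDistribution(
            "tables.transitions.stage_progression.1",
            "lognormal",
            (float(np.log(0.40)), 0.15),
            upper=0.74,
        ),
        ParameterDistribution(
            "tables.transitions.stage_progression.2",
            "lognormal",
            (float(np.log(0.45)), 0.15),
            upper=0.79,
        ),
    ]


@dataclass(frozen=True)
class PSAConfig:
    n_runs: int = 500
    n_patients: int = 100_000
    master_seed: int = 0
    strategies: tuple[Strategy, ...] = ()
    wtp_grid: tuple[float, ...] = (0.0, 10_000.0, 20_000.0, 30_000.0, 50_000.0)

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.n_patients < 1:
            raise ConfigurationError("n_runs and n_patients must be >= 1")


@dataclass
class PSAResult:
    """Per-run, per-strategy outcomes in long form.

    Columns: run, strategy, cost, qaly, ly, crc_deaths, usc_referrals,
    usc_crc_diagnoses (per the economics scale).
    """

    table: pd.DataFrame
    config: PSAConfig
    econ: EconomicsConfig

    @property
    def n_runs(self) -> int:
        return self.table["run"].nunique()

    def strategy_values(self, strategy: str, column: str) -> np.ndarray:
        t = self.table
        return t.loc[t["strategy"] == strategy, column].to_numpy()

    def nmb(self, wtp: float) -> pd.DataFrame:
        """run x strategy net monetary benefit matrix."""
        t = self.table.assign(nmb=lambda d: wtp * d["qaly"] - d["cost"])
        return t.pivot(index="run", columns="strategy", values="nmb")


def run_psa(
    bundle: ModelBundle,
    psa_cfg: PSAConfig,
    dists: list[ParameterDistribution] | None = None,
) -> PSAResult:
    """Full PSA: one parameter draw + one fresh cohort per run.

    Run r uses seeds derived from (master_seed, r), so results are
    reproducible and independent of execution order.
    """
    if not psa_cfg.strategies:
        raise ConfigurationError("PSA needs at least one strategy")
    if dists is None:
        dists = default_psa_distributions()
    rows = []
    for r in range(psa_cfg.n_runs):
        ss = np.random.SeedSequence([psa_cfg.master_seed, r])
        param_seed, cohort_seed = (
            int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)
        )
        try:
            values = sample_parameters(dists, np.random.default_rng(param_seed))
            run_bundle = apply_parameters(bundle, values)
            _, evals = evaluate_strategies(
                run_bundle, list(psa_cfg.strategies), psa_cfg.n_patients, cohort_seed
            )
        except Exception as exc:  # noqa: BLE001 - annotate run index
            raise RuntimeError(f"PSA run {r} failed: {exc}") from exc
        for e in evals:
            rows.append(
                {
                    "run": r,
                    "strategy": e.strategy.label,
                    "cost": e.outcome.cost,
                    "qaly": e.outcome.qaly,
                    "ly": e.outcome.ly,
                    "crc_deaths": e.outcome.crc_deaths,
                    "usc_referrals": e.outcome.usc_referrals,
                    "usc_crc_diagnoses": e.outcome.usc_crc_diagnoses,
                }
            )
    return PSAResult(pd.DataFrame(rows), psa_cfg, bundle.econ)


def probability_cost_effective(result: PSAResult, wtp: float) -> dict[str, float]:
    """Fraction of runs each strategy attains the maximum NMB (ties split)."""
    nmb = result.nmb(wtp)
    probs = dict.fromkeys(nmb.columns, 0.0)
    n = len(nmb)
    for _, row in nmb.iterrows():
        best = row.max()
        winners = row.index[np.isclose(row.to_numpy(dtype=float), best, rtol=0, atol=1e-9)]
        for w in winners:
            probs[w] += 1.0 / (len(winners) * n)
    return probs


def ceac(result: PSAResult, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a willingness-to-pay grid."""
    grid = list(wtp_grid) if wtp_grid is not None else list(result.config.wtp_grid)
    if not grid:
        raise ValueError("empty willingness-to-pay grid")
    rows = []
    for wtp in grid:
        for strategy, p in probability_cost_effective(result, wtp).items():
            rows.append({"wtp": wtp, "strategy": strategy, "probability": p})
    return pd.DataFrame(rows)


def credible_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Empirical central credible interval (linear-interpolation percentiles)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for a credible interval")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(x, [100 * alpha, 100 * (1 - alpha)], method="linear")
    return float(lo), float(hi)
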