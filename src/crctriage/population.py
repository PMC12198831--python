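"""Synthetic symptomatic primary-care populations.

A cohort of patients who presented to their GP with lower-GI symptoms and
returned a faecal immunochemical test (FIT) is generated from *aggregate*
inputs only: per-variable quantile grids (the marginal distributions) and a
correlation matrix on a latent Gaussian scale.  Correlated standard normals
are drawn, each column is pushed through the normal CDF to a uniform rank,
and the rank is refitted onto the variable's quantile grid by monotone
interpolation.  Binary variables (sex) use a latent-threshold normal so a
single sampling mechanism covers every covariate.

Because the rank/refit step is invariant under monotone transforms, heavily
right-skewed variables such as FIT are reproduced faithfully without any
parametric distributional assumption.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarginalSpec",
    "PopulationConfig",
    "Person",
    "Population",
    "ConfigurationError",
    "generate_population",
    "apply_quantile_refit",
    "summarize_population",
    "make_toy_cohort",
]

SEX_FEMALE = "F"
SEX_MALE = "M"


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass(frozen=True)
class MarginalSpec:
    """Marginal distribution of one covariate as a quantile grid.

    Parameters
    ----------
    variable_name:
        Column name (``age``, ``fit``, or a blood analyte).
    quantile_grid:
        Ordered ``(probability, value)`` pairs; probabilities strictly
        increasing in [0, 1], values non-decreasing.
    transform:
        Monotone transform nominally applied before correlation modelling
        (``identity``, ``log``, ``logit``).  The rank-based copula used here
        is invariant under monotone transforms, so the field documents the
        scale of the aggregate inputs rather than changing the sampler.
    binary:
        If True the variable is 0/1 via a latent threshold: the first grid
        probability is P(value == first grid value).
    lower_bound, upper_bound:
        Optional clips in the variable's own units.
    """

    variable_name: str
    quantile_grid: tuple[tuple[float, float], ...]
    transform: str = "identity"
    binary: bool = False
    lower_bound: float | None = None
    upper_bound: float | None = None

    def __post_init__(self) -> None:
        grid = tuple((float(p), float(v)) for p, v in self.quantile_grid)
        object.__setattr__(self, "quantile_grid", grid)
        if len(grid) == 0:
            raise ConfigurationError(
                f"{self.variable_name}: quantile grid is empty"
            )
        probs = np.array([p for p, _ in grid])
        vals = np.array([v for _, v in grid])
        if np.any(probs < 0) or np.any(probs > 1):
            raise ConfigurationError(
                f"{self.variable_name}: grid probabilities outside [0, 1]"
            )
        if len(probs) > 1 and np.any(np.diff(probs) <= 0):
            raise ConfigurationError(
                f"{self.variable_name}: grid probabilities not strictly increasing"
            )
        if np.any(np.diff(vals) < 0):
            raise ConfigurationError(
                f"{self.variable_name}: grid values decrease"
            )
        if self.lower_bound is not None and self.lower_bound > vals.min():
            raise ConfigurationError(
                f"{self.variable_name}: lower bound above smallest grid value"
            )
        if self.upper_bound is not None and self.upper_bound < vals.max():
            raise ConfigurationError(
                f"{self.variable_name}: upper bound below largest grid value"
            )

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([p for p, _ in self.quantile_grid])

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.quantile_grid])


@dataclass(frozen=True)
class PopulationConfig:
    """Everything needed to draw one synthetic cohort.

    ``marginals`` must include ``age``, ``sex`` (binary, 0 = female,
    1 = male) and ``fit``; remaining entries are blood-count analytes.
    ``correlation`` is the latent-normal correlation matrix in the order of
    ``marginals``.  ``recent_fbc_probability`` is the share of patients with
    a recent full blood count on record (0.91 in the source population).
    """

    cohort_label: str
    marginals: tuple[MarginalSpec, ...]
    correlation: tuple[tuple[float, ...], ...]
    recent_fbc_probability: float = 0.91
    n: int = 1000
    seed: int = 0
    age_bounds: tuple[float, float] = (18.0, 100.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "marginals", tuple(self.marginals))
        corr = np.asarray(self.correlation, dtype=float)
        k = len(self.marginals)
        if corr.shape != (k, k):
            raise ConfigurationError(
                f"correlation matrix shape {corr.shape} != ({k}, {k})"
            )
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ConfigurationError("correlation matrix not symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ConfigurationError("correlation diagonal not 1")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigurationError("correlation matrix not positive semidefinite")
        if not 0.0 <= self.recent_fbc_probability <= 1.0:
            raise ConfigurationError("recent_fbc_probability outside [0, 1]")
        if self.n <= 0:
            raise ConfigurationError("n must be positive")
        object.__setattr__(
            self, "correlation", tuple(tuple(float(v) for v in row) for row in corr)
        )

    @property
    def variable_names(self) -> list[str]:
        return [m.variable_name for m in self.marginals]

    def fingerprint(self) -> str:
        payload = {
            "cohort_label": self.cohort_label,
            "marginals": [
                {
                    "name": m.variable_name,
                    "grid": list(m.quantile_grid),
                    "transform": m.transform,
                    "binary": m.binary,
                    "lo": m.lower_bound,
                    "hi": m.upper_bound,
                }
                for m in self.marginals
            ],
            "correlation": [list(r) for r in self.correlation],
            "recent_fbc_probability": self.recent_fbc_probability,
            "n": self.n,
            "seed": self.seed,
            "age_bounds": list(self.age_bounds),
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_n_seed(self, n: int, seed: int) -> "PopulationConfig":
        return replace(self, n=n, seed=seed)


@dataclass(frozen=True)
class Person:
    id: int
    age: float
    sex: str  # "F" or "M"
    fit_value: float
    blood_panel: dict[str, float] = field(default_factory=dict)
    has_recent_fbc: bool = True

    def __post_init__(self) -> None:
        if self.fit_value < 0:
            raise ValueError("fit_value must be >= 0")
        if self.sex not in (SEX_FEMALE, SEX_MALE):
            raise ValueError("sex must be 'F' or 'M'")

    def covariate(self, name: str) -> float:
        """Named covariate for risk models; sex is coded male = 1."""
        if name == "age":
            return self.age
        if name == "sex":
            return 1.0 if self.sex == SEX_MALE else 0.0
        if name == "fit":
            return self.fit_value
        try:
            return self.blood_panel[name]
        except KeyError:
            raise KeyError(f"person {self.id} lacks covariate '{name}'") from None


class Population:
    """A cohort stored as a DataFrame, with Person views for small fixtures.

    Columns: ``id, age, sex, fit, <analyte...>, has_recent_fbc`` with sex
    encoded ``F``/``M``.
    """

    def __init__(self, df: pd.DataFrame, config_fingerprint: str = ""):
        if df["id"].duplicated().any():
            raise ValueError("person ids must be unique")
        self.df = df.reset_index(drop=True)
        self.config_fingerprint = config_fingerprint

    def __len__(self) -> int:
        return len(self.df)

    @property
    def analytes(self) -> list[str]:
        reserved = {"id", "age", "sex", "fit", "has_recent_fbc"}
        return [c for c in self.df.columns if c not in reserved]

    def covariate_column(self, name: str) -> np.ndarray:
        """Vectorised covariate lookup; sex coded male = 1."""
        if name == "sex":
            return (self.df["sex"].to_numpy() == SEX_MALE).astype(float)
        if name == "fit":
            return self.df["fit"].to_numpy(dtype=float)
        if name not in self.df.columns:
            raise KeyError(f"population lacks covariate '{name}'")
        return self.df[name].to_numpy(dtype=float)

    def persons(self) -> list[Person]:
        out = []
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            panel = {
                k: float(v)
                for k, v in d.items()
                if k not in ("id", "age", "sex", "fit", "has_recent_fbc")
            }
            out.append(
                Person(
                    id=int(d["id"]),
                    age=float(d["age"]),
                    sex=str(d["sex"]),
                    fit_value=float(d["fit"]),
                    blood_panel=panel,
                    has_recent_fbc=bool(d["has_recent_fbc"]),
                )
            )
        return out

    @classmethod
    def from_persons(cls, persons: list[Person], fingerprint: str = "") -> "Population":
        analytes = sorted({k for p in persons for k in p.blood_panel})
        rows = []
        for p in persons:
            row = {
                "id": p.id,
                "age": p.age,
                "sex": p.sex,
                "fit": p.fit_value,
                "has_recent_fbc": p.has_recent_fbc,
            }
            for a in analytes:
                row[a] = p.blood_panel.get(a, np.nan)
            rows.append(row)
        cols = ["id", "age", "sex", "fit", *analytes, "has_recent_fbc"]
        return cls(pd.DataFrame(rows)[cols], fingerprint)

    def write_csv(self, path) -> None:
        cols = ["id", "age", "sex", "fit", *self.analytes, "has_recent_fbc"]
        self.df[cols].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "Population":
        df = pd.read_csv(path)
        df["has_recent_fbc"] = df["has_recent_fbc"].astype(bool)
        return cls(df)


def apply_quantile_refit(raw_values, spec: MarginalSpec) -> np.ndarray:
    """Monotone rank-preserving remap of values onto a quantile grid.

    Values already inside [0, 1] are interpreted as cumulative ranks and
    pushed directly through the grid's inverse CDF (linear interpolation
    between grid points, clipped to the spec bounds).  Values outside [0, 1]
    are first converted to plotting-position ranks ``(r - 0.5) / n`` so that
    arbitrary raw draws can be refitted; either way the output ordering
    matches the input ordering.
    """
    x = np.asarray(raw_values, dtype=float)
    if x.size and (x.min() < 0.0 or x.max() > 1.0):
        order = np.argsort(x, kind="stable")
        ranks = np.empty(x.size, dtype=float)
        ranks[order] = (np.arange(x.size) + 0.5) / x.size
        u = ranks.reshape(x.shape)
    else:
        u = x
    probs, vals = spec.probabilities, spec.values
    out = np.interp(u, probs, vals)
    lo = spec.lower_bound if spec.lower_bound is not None else vals[0]
    hi = spec.upper_bound if spec.upper_bound is not None else vals[-1]
    return np.clip(out, lo, hi)


def generate_population(config: PopulationConfig) -> Population:
    """Draw a synthetic cohort from aggregate marginals and correlations.

    Gaussian copula: z ~ MVN(0, R); u = Phi(z); each u column is refitted
    onto its marginal quantile grid (binary columns threshold the latent
    uniform).  Deterministic given (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    k = len(config.marginals)
    corr = np.asarray(config.correlation)
    # eigen-based square root tolerates semidefinite matrices
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    chol_like = v * np.sqrt(w)
    z = rng.standard_normal((config.n, k)) @ chol_like.T
    u = stats.norm.cdf(z)

    data: dict[str, np.ndarray] = {}
    for j, spec in enumerate(config.marginals):
        if spec.binary:
            p0 = spec.probabilities[0]
            v0, v1 = spec.values[0], spec.values[-1]
            data[spec.variable_name] = np.where(u[:, j] <= p0, v0, v1)
        else:
            data[spec.variable_name] = apply_quantile_refit(u[:, j], spec)

    if "age" in data:
        data["age"] = np.clip(data["age"], *config.age_bounds)

    df = pd.DataFrame({"id": np.arange(1, config.n + 1)})
    df["age"] = data.pop("age")
    sex_num = data.pop("sex")
    df["sex"] = np.where(sex_num >= 0.5, SEX_MALE, SEX_FEMALE)
    df["fit"] = data.pop("fit")
    for name, col in data.items():
        df[name] = col
    df["has_recent_fbc"] = rng.random(config.n) < config.recent_fbc_probability
    return Population(df, config.fingerprint())


def summarize_population(pop: Population) -> pd.DataFrame:
    """Per-variable summary (min/quantiles/mean/max) plus the sex split.

    Returns a tidy frame with one row per (variable, statistic); the sex
    split appears as ``sex`` rows with statistics ``share_F``/``share_M``.
    """
    if len(pop) == 0:
        raise ValueError("cannot summarize an empty population")
    num_cols = ["age", "fit", *pop.analytes]
    records = []
    for col in num_cols:
        x = pop.df[col].to_numpy(dtype=float)
        stats_map = {
            "min": np.min(x),
            "q10": np.quantile(x, 0.10),
            "q25": np.quantile(x, 0.25),
            "median": np.quantile(x, 0.50),
            "q75": np.quantile(x, 0.75),
            "q90": np.quantile(x, 0.90),
            "mean": np.mean(x),
            "max": np.max(x),
        }
        for k, v in stats_map.items():
            records.append({"variable": col, "statistic": k, "value": float(v)})
    sex = pop.df["sex"]
    for code in (SEX_FEMALE, SEX_MALE):
        records.append(
            {
                "variable": "sex",
                "statistic": f"share_{code}",
                "value": float((sex == code).mean()),
            }
        )
    records.append(
        {
            "variable": "has_recent_fbc",
            "statistic": "share_true",
            "value": float(pop.df["has_recent_fbc"].mean()),
        }
    )
    return pd.DataFrame.from_records(records)


def make_toy_cohort() -> Population:
    """Fixed five-person cohort for hand computation.

    Spans FIT below/above the 10 µg Hb/g referral threshold, ages below 50
    and 70+, both sexes, and both recent-blood-count states:

    ==  ====  ===  =====  ============  ====  ==============
    id  age   sex  FIT    haemoglobin   MCV   recent FBC?
    ==  ====  ===  =====  ============  ====  ==============
    1   42    F    2.0    138           90    yes
    2   48    M    15.0   128           84    no
    3   61    F    9.9    141           92    yes
    4   74    M    120.0  110           78    yes
    5   85    F    35.0   125           88    no
    ==  ====  ===  =====  ============  ====  ==============
    """
    persons = [
        Person(1, 42.0, SEX_FEMALE, 2.0, {"haemoglobin": 138.0, "mcv": 90.0}, True),
        Person(2, 48.0, SEX_MALE, 15.0, {"haemoglobin": 128.0, "mcv": 84.0}, False),
        Person(3, 61.0, SEX_FEMALE, 9.9, {"haemoglobin": 141.0, "mcv": 92.0}, True),
        Person(4, 74.0, SEX_MALE, 120.0, {"haemoglobin": 110.0, "mcv": 78.0}, True),
        Person(5, 85.0, SEX_FEMALE, 35.0, {"haemoglobin": 125.0, "mcv": 88.0}, False),
    ]
    return Population.from_persons(persons, fingerprint="toy-cohort-v1")
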