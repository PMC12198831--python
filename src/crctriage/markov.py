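"""Lifetime natural-history model with annual cycles.

Each person is followed from their baseline age to age 100 (or absorption in
death) through an annual-cycle state-transition model.  CRC cases progress
through stages I-IV during any diagnostic delay — the *stage shift* that
makes delay harmful — using a continuous-time chain whose rates come from
the annual progression probabilities (lambda = -ln(1 - p)).  After
diagnosis the stage is fixed and annual CRC mortality depends on stage, sex,
age band and time since diagnosis; other-cause mortality follows a life
table.  Utilities and costs accrue per cycle and are discounted annually.

Per-person traces are expected-value (fractional state occupancy), so the
lifetime model is deterministic given its inputs; all randomness lives in
population generation, disease allocation and the short-term pathway.
Convention: accrual at cycle start, year 0 undiscounted, no half-cycle
correction, survival-table rows beyond year 10 since diagnosis reuse the
year-10 row, age is capped at 100 where death is certain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import ConfigurationError, Population
from .disease import BaselineStates, CRC_STAGES, STAGE_NONE
from .pathway import DelayModel, DiagnosticOutcomes, ScenarioFlags

__all__ = [
    "TransitionParams",
    "SurvivalTable",
    "LifeTable",
    "UtilityCostTable",
    "ModelTables",
    "LifeCourseResult",
    "LifeCourseResults",
    "discount",
    "progress_during_delay",
    "stage_shift_batch",
    "run_lifecourse",
    "lifecourse_batch",
    "healthy_trace",
    "ibd_lifecourse_adjustment",
    "adenoma_conversion_trace",
    "adenoma_lifecourse",
]

MAX_AGE = 100
_SEX_IDX = {"F": 0, "M": 1}
_PHASES = ("year1", "subsequent")


# --------------------------------------------------------------------------
# parameter tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionParams:
    """Annual progression probabilities.

    ``stage_progression`` = (I->II, II->III, III->IV); stage IV is
    absorbing.  ``fast_stage_progression`` are the scenario upper bounds for
    faster progression in symptomatic patients and must dominate the base
    values.  ``adenoma_progression`` = (low->high, high->CRC stage I), used
    only when adenoma detection is switched on.
    """

    stage_progression: tuple[float, float, float] = (0.35, 0.40, 0.45)
    fast_stage_progression: tuple[float, float, float] = (0.70, 0.75, 0.80)
    adenoma_progression: tuple[float, float] = (0.02, 0.05)

    def __post_init__(self) -> None:
        for name in ("stage_progression", "fast_stage_progression", "adenoma_progression"):
            vals = getattr(self, name)
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ConfigurationError(f"{name} outside [0, 1]")
        if any(f < b for f, b in zip(self.fast_stage_progression, self.stage_progression)):
            raise ConfigurationError("fast-mode progression must dominate base values")

    def effective_stage_progression(self, fast: bool) -> tuple[float, float, float]:
        return self.fast_stage_progression if fast else self.stage_progression


class SurvivalTable:
    """Annual CRC death probability by (stage, sex, age band, year since dx).

    ``band_edges`` are ascending band lower bounds (the last band is open);
    ``probs`` has shape (4 stages, 2 sexes [F, M], n_bands, 10 years).
    """

    def __init__(self, band_edges: tuple[float, ...], probs: np.ndarray):
        probs = np.asarray(probs, dtype=float)
        if probs.shape[:2] != (4, 2) or probs.shape[3] != 10:
            raise ConfigurationError(
                f"survival probs must have shape (4, 2, n_bands, 10); got {probs.shape}"
            )
        if probs.shape[2] != len(band_edges):
            raise ConfigurationError("band count mismatch")
        if np.any((probs < 0) | (probs > 1)):
            raise ConfigurationError("survival probabilities outside [0, 1]")
        self.band_edges = tuple(float(b) for b in band_edges)
        self.probs = probs

    def band_index(self, age) -> np.ndarray:
        return np.clip(
            np.searchsorted(self.band_edges, np.asarray(age), side="right") - 1,
            0,
            len(self.band_edges) - 1,
        )

    def lookup(self, stage_idx, sex_idx, age, year_since_dx) -> np.ndarray:
        """Vectorised annual CRC-death probability; years > 10 use year 10."""
        ysd = np.clip(np.asarray(year_since_dx) - 1, 0, 9)
        return self.probs[
            np.asarray(stage_idx), np.asarray(sex_idx), self.band_index(age), ysd
        ]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        edges = [*self.band_edges, math.inf]
        for si, stage in enumerate(CRC_STAGES):
            for xi, sex in enumerate(("F", "M")):
                for bi in range(len(self.band_edges)):
                    lo, hi = edges[bi], edges[bi + 1]
                    band = f"{lo:g}+" if math.isinf(hi) else f"{lo:g}-{hi:g}"
                    for y in range(10):
                        rows.append(
                            {
                                "stage": stage,
                                "sex": sex,
                                "age_band": band,
                                "year_since_dx": y + 1,
                                "annual_death_prob": self.probs[si, xi, bi, y],
                            }
                        )
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SurvivalTable":
        def band_lo(b: str) -> float:
            return float(str(b).rstrip("+").split("-")[0])

        bands = sorted(df["age_band"].unique(), key=band_lo)
        edges = tuple(band_lo(b) for b in bands)
        probs = np.full((4, 2, len(bands), 10), np.nan)
        stage_i = {s: i for i, s in enumerate(CRC_STAGES)}
        band_i = {b: i for i, b in enumerate(bands)}
        for r in df.itertuples(index=False):
            probs[
                stage_i[r.stage], _SEX_IDX[r.sex], band_i[r.age_band], int(r.year_since_dx) - 1
            ] = r.annual_death_prob
        if np.isnan(probs).any():
            raise ConfigurationError("survival table has missing (stage, sex, band, year) cells")
        return cls(edges, probs)


class LifeTable:
    """All-cause annual death probability q(age, sex), ages 0-100; q(100) = 1."""

    def __init__(self, q: np.ndarray):
        q = np.asarray(q, dtype=float)
        if q.shape != (MAX_AGE + 1, 2):
            raise ConfigurationError(f"life table must have shape (101, 2); got {q.shape}")
        if np.any((q < 0) | (q > 1)):
            raise ConfigurationError("life-table probabilities outside [0, 1]")
        q = q.copy()
        q[MAX_AGE, :] = 1.0
        self.q = q

    def lookup(self, age, sex_idx) -> np.ndarray:
        a = np.clip(np.asarray(age, dtype=int), 0, MAX_AGE)
        return self.q[a, np.asarray(sex_idx)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for age in range(MAX_AGE + 1):
            for xi, sex in enumerate(("F", "M")):
                rows.append({"age": age, "sex": sex, "annual_death_prob": self.q[age, xi]})
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LifeTable":
        q = np.full((MAX_AGE + 1, 2), np.nan)
        for r in df.itertuples(index=False):
            q[int(r.age), _SEX_IDX[r.sex]] = r.annual_death_prob
        if np.isnan(q).any():
            raise ConfigurationError("life table has missing (age, sex) cells")
        return cls(q)


@dataclass(frozen=True)
class UtilityCostTable:
    """Utilities and annual costs (GBP 2023).

    General-population utility by age band and sex; CRC utility multipliers
    and annual costs by stage and phase (first year since diagnosis vs
    subsequent years), plus a per-stage terminal cost charged in the cycle
    of CRC death; IBD annual cost and utility multiplier for routine vs
    complicated (delayed-diagnosis) disease courses.
    """

    gen_band_edges: tuple[float, ...] = (18.0, 40.0, 55.0, 65.0, 75.0)
    gen_utility: tuple[tuple[float, float], ...] = (
        (0.92, 0.93),
        (0.88, 0.89),
        (0.84, 0.85),
        (0.81, 0.82),
        (0.76, 0.77),
    )
    stage_utility_mult: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "I": (0.90, 0.95),
            "II": (0.85, 0.92),
            "III": (0.75, 0.85),
            "IV": (0.60, 0.65),
        }
    )
    stage_cost: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "I": (15000.0, 1000.0),
            "II": (20000.0, 1500.0),
            "III": (28000.0, 3500.0),
            "IV": (35000.0, 8000.0),
        }
    )
    terminal_cost: dict[str, float] = field(
        default_factory=lambda: {"I": 12000.0, "II": 12000.0, "III": 12000.0, "IV": 12000.0}
    )
    ibd_cost: dict[str, float] = field(
        default_factory=lambda: {"routine": 1500.0, "complicated": 4000.0}
    )
    ibd_utility_mult: dict[str, float] = field(
        default_factory=lambda: {"routine": 0.92, "complicated": 0.85}
    )

    def __post_init__(self) -> None:
        if len(self.gen_utility) != len(self.gen_band_edges):
            raise ConfigurationError("one utility row per age band required")
        for row in self.gen_utility:
            if any(not 0.0 <= u <= 1.0 for u in row):
                raise ConfigurationError("utilities must lie in [0, 1]")
        for table in (self.stage_utility_mult, self.ibd_utility_mult):
            vals = (
                [v for pair in table.values() for v in (pair if isinstance(pair, tuple) else (pair,))]
            )
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ConfigurationError("utility multipliers must lie in [0, 1]")
        for table in (self.stage_cost, self.terminal_cost, self.ibd_cost):
            vals = [v for pair in table.values() for v in (pair if isinstance(pair, tuple) else (pair,))]
            if any(v < 0 for v in vals):
                raise ConfigurationError("costs must be >= 0")

    def general_utility(self, age, sex_idx) -> np.ndarray:
        bi = np.clip(
            np.searchsorted(self.gen_band_edges, np.asarray(age), side="right") - 1,
            0,
            len(self.gen_band_edges) - 1,
        )
        table = np.asarray(self.gen_utility)
        return table[bi, np.asarray(sex_idx)]

    def stage_mult_array(self) -> np.ndarray:
        """(4 stages, 2 phases) utility multipliers."""
        return np.array([self.stage_utility_mult[s] for s in CRC_STAGES])

    def stage_cost_array(self) -> np.ndarray:
        return np.array([self.stage_cost[s] for s in CRC_STAGES])

    def terminal_cost_array(self) -> np.ndarray:
        return np.array([self.terminal_cost[s] for s in CRC_STAGES])


@dataclass(frozen=True)
class ModelTables:
    """Bundle of every long-term model input."""

    transitions: TransitionParams = TransitionParams()
    survival: "SurvivalTable" = None  # type: ignore[assignment]
    life: "LifeTable" = None  # type: ignore[assignment]
    utility_cost: UtilityCostTable = UtilityCostTable()


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------


def discount(amount, years_from_baseline, rate: float):
    """Annual discounting: amount / (1 + rate)^floor(years); year 0 undiscounted."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    t = np.floor(np.asarray(years_from_baseline, dtype=float))
    out = np.asarray(amount, dtype=float) / (1.0 + rate) ** t
    return out if out.ndim else float(out)


def _stage_generator(probs3) -> np.ndarray:
    """CTMC generator for the I->II->III->IV chain from annual probabilities."""
    lam = [-math.log(1.0 - p) if p < 1.0 else math.inf for p in probs3]
    if any(math.isinf(v) for v in lam):
        raise ConfigurationError("annual progression probability of 1 is not supported")
    q = np.zeros((4, 4))
    for i, l in enumerate(lam):
        q[i, i] = -l
        q[i, i + 1] = l
    return q


def stage_shift_batch(stage_dist: np.ndarray, delays: np.ndarray, probs3) -> np.ndarray:
    """Expected stage distribution after continuous exposure of `delays` years.

    Row-wise: dist @ expm(Q * d), computed through the eigendecomposition of
    the (upper-bidiagonal) generator so all persons are handled in one
    vectorised pass; falls back to scipy expm if rates nearly coincide.
    """
    stage_dist = np.atleast_2d(np.asarray(stage_dist, dtype=float))
    delays = np.asarray(delays, dtype=float)
    if np.any(delays < 0):
        raise ValueError("delay must be >= 0")
    q = _stage_generator(probs3)
    eigvals = np.diag(q)
    if np.min(np.abs(np.subtract.outer(eigvals, eigvals)[~np.eye(4, dtype=bool)])) < 1e-10:
        from scipy.linalg import expm

        out = np.vstack([row @ expm(q * d) for row, d in zip(stage_dist, delays)])
    else:
        w, v = np.linalg.eig(q.T)  # act on column vectors of dist^T
        vinv = np.linalg.inv(v)
        # dist(d) = dist0 @ V' exp(w d) V'^-1 with V' from q (right action)
        wq, vq = np.linalg.eig(q)
        vqinv = np.linalg.inv(vq)
        tmp = stage_dist @ vq  # (m, 4)
        tmp = tmp * np.exp(np.outer(delays, wq))
        out = (tmp @ vqinv).real
    out = np.clip(out, 0.0, None)
    return out / out.sum(axis=1, keepdims=True)


def progress_during_delay(
    stage: str,
    delay: float,
    params: TransitionParams,
    mode: str = "expected",
    rng: np.random.Generator | None = None,
    fast: bool = False,
):
    """Stage shift for one CRC case during its diagnostic delay.

    ``expected`` mode returns the stage distribution (length-4 array over
    I-IV); ``sampled`` mode draws a single stage.  Delay 0 is the identity.
    """
    if delay < 0:
        raise ValueError("delay must be >= 0")
    idx = CRC_STAGES.index(stage)
    onehot = np.zeros(4)
    onehot[idx] = 1.0
    if delay == 0:
        dist = onehot
    else:
        dist = stage_shift_batch(
            onehot, np.array([delay]), params.effective_stage_progression(fast)
        )[0]
    if mode == "expected":
        return dist
    if mode == "sampled":
        if rng is None:
            raise ValueError("sampled mode needs an rng")
        return CRC_STAGES[int(rng.choice(4, p=dist))]
    raise ValueError(f"unknown mode '{mode}'")


# --------------------------------------------------------------------------
# results containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeCourseResult:
    person_id: int
    discounted_cost: float
    discounted_qaly: float
    discounted_ly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    undiscounted_ly: float
    crc_death_probability: float
    stage_at_diagnosis: str  # modal stage, or "none"


class LifeCourseResults:
    """Per-person lifetime results (population order)."""

    COLUMNS = [
        "person_id",
        "discounted_cost",
        "discounted_qaly",
        "discounted_ly",
        "undiscounted_cost",
        "undiscounted_qaly",
        "undiscounted_ly",
        "crc_death_probability",
        "stage_at_diagnosis",
    ]

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> list[LifeCourseResult]:
        return [
            LifeCourseResult(
                int(r.person_id),
                float(r.discounted_cost),
                float(r.discounted_qaly),
                float(r.discounted_ly),
                float(r.undiscounted_cost),
                float(r.undiscounted_qaly),
                float(r.undiscounted_ly),
                float(r.crc_death_probability),
                str(r.stage_at_diagnosis),
            )
            for r in self.df.itertuples(index=False)
        ]


# --------------------------------------------------------------------------
# healthy (no colorectal disease) trace, per (age, sex) cell
# --------------------------------------------------------------------------


def healthy_trace(
    age0: int,
    sex_idx: int,
    life: LifeTable,
    uc: UtilityCostTable,
    rate: float,
    horizon_age: int = MAX_AGE,
) -> dict[str, float]:
    """Closed accrual of LY/QALY for a disease-free person.

    Survival follows the life table; utility the general-population table.
    Returns discounted and undiscounted LY and QALY (the discounted pair
    doubles as the annuity factors used by the IBD cost/utility streams).
    Accrual covers ages [age0, horizon_age): with zero mortality and unit
    utility, LY = QALY = horizon_age - age0.
    """
    ly_d = qaly_d = ly_u = qaly_u = 0.0
    alive = 1.0
    for t in range(0, max(horizon_age - age0, 0)):
        age = age0 + t
        if alive <= 0:
            break
        u = float(uc.general_utility(age, sex_idx))
        dfac = 1.0 / (1.0 + rate) ** t
        ly_d += alive * dfac
        qaly_d += alive * u * dfac
        ly_u += alive
        qaly_u += alive * u
        alive *= 1.0 - float(life.lookup(age, sex_idx))
    return {"ly_d": ly_d, "qaly_d": qaly_d, "ly_u": ly_u, "qaly_u": qaly_u}


# --------------------------------------------------------------------------
# the annual-cycle engine
# --------------------------------------------------------------------------


def lifecourse_batch(
    pop: Population,
    baseline_states: BaselineStates,
    diag: DiagnosticOutcomes,
    tables: ModelTables,
    econ_cfg,
    scenario: ScenarioFlags = ScenarioFlags(),
    delay_model: DelayModel = DelayModel(),
    adenoma_crc_extra_cost: float = 0.0,
    record_mass: bool = False,
):
    """Run the lifetime model for a whole cohort.

    Disease-free persons are resolved per unique (age, sex) cell; CRC cases
    get individual expected-value traces (pre-diagnosis survival, stage
    shift over the personalised delay, stage-specific mortality, costs and
    utility multipliers after diagnosis).  IBD and adenoma adjustments are
    added when the scenario switches them on.  ``econ_cfg`` needs a
    ``discount_rate`` attribute (or pass a float).
    """
    rate = econ_cfg if isinstance(econ_cfg, (int, float)) else econ_cfg.discount_rate
    n = len(pop)
    if len(baseline_states) != n or len(diag) != n:
        raise ValueError("population, states and diagnostic outcomes must align")
    uc = tables.utility_cost
    life = tables.life

    age0 = np.floor(pop.df["age"].to_numpy(dtype=float)).astype(int)
    age0 = np.clip(age0, 0, MAX_AGE)
    sex_idx = np.where(pop.df["sex"].to_numpy() == "M", 1, 0)

    cost_d = np.zeros(n)
    qaly_d = np.zeros(n)
    ly_d = np.zeros(n)
    cost_u = np.zeros(n)
    qaly_u = np.zeros(n)
    ly_u = np.zeros(n)
    crc_death = np.zeros(n)
    stage_dx = np.full(n, STAGE_NONE, dtype=object)

    # ---- disease-free persons via (age, sex) cells ----
    has_crc = baseline_states.has_crc
    healthy = ~has_crc
    cells: dict[tuple[int, int], dict[str, float]] = {}
    for a, s in {(int(a), int(s)) for a, s in zip(age0[healthy], sex_idx[healthy])}:
        cells[(a, s)] = healthy_trace(a, s, life, uc, rate)
    if healthy.any():
        idx = np.where(healthy)[0]
        for i in idx:
            c = cells[(int(age0[i]), int(sex_idx[i]))]
            ly_d[i] = c["ly_d"]
            qaly_d[i] = c["qaly_d"]
            ly_u[i] = c["ly_u"]
            qaly_u[i] = c["qaly_u"]

    mass_history = []

    # ---- CRC cases, vectorised over cases with an annual loop ----
    if has_crc.any():
        ci = np.where(has_crc)[0]
        m = len(ci)
        a0 = age0[ci]
        sx = sex_idx[ci]
        delays = diag.df["crc_diagnosis_delay"].to_numpy(dtype=float)[ci]
        base_stage = baseline_states.crc_stage[ci]
        onehot = np.zeros((m, 4))
        for k, s in enumerate(base_stage):
            onehot[k, CRC_STAGES.index(s)] = 1.0
        probs3 = tables.transitions.effective_stage_progression(scenario.fast_transitions)
        pi = np.where(delays[:, None] > 0, stage_shift_batch(onehot, delays, probs3), onehot)
        pi = pi / pi.sum(axis=1, keepdims=True)
        stage_dx[ci] = np.asarray(CRC_STAGES, dtype=object)[np.argmax(pi, axis=1)]

        # The diagnosed trace starts at baseline with the stage distribution
        # reached by the end of the personal delay: harm from delay is the
        # stage shift itself, so longer delay can never look beneficial by
        # merely postponing the survival clock.
        occ = pi.copy()
        dead_other = np.zeros(m)
        dead_crc = np.zeros(m)
        mult = uc.stage_mult_array()  # (4, 2)
        scost = uc.stage_cost_array()
        tcost = uc.terminal_cost_array()

        horizon = int(MAX_AGE - a0.min())
        for t in range(horizon + 1):
            age_t = np.minimum(a0 + t, MAX_AGE)
            post = a0 + t < MAX_AGE
            dfac = 1.0 / (1.0 + rate) ** t
            u_gen = uc.general_utility(age_t, sx)
            q_oc = life.lookup(age_t, sx)

            if post.any():
                ysd = np.full(m, t + 1)
                phase = np.where(ysd == 1, 0, 1)
                o = occ[post]  # (k, 4)
                k_idx = ci[post]
                ly_d[k_idx] += o.sum(axis=1) * dfac
                ly_u[k_idx] += o.sum(axis=1)
                um = mult[:, phase[post]].T  # (k, 4)
                qaly_contrib = (o * um).sum(axis=1) * u_gen[post]
                qaly_d[k_idx] += qaly_contrib * dfac
                qaly_u[k_idx] += qaly_contrib
                cc = scost[:, phase[post]].T
                cost_contrib = (o * cc).sum(axis=1)
                cost_d[k_idx] += cost_contrib * dfac
                cost_u[k_idx] += cost_contrib

                p_crc = np.stack(
                    [
                        tables.survival.lookup(
                            np.full(int(post.sum()), si), sx[post], age_t[post], ysd[post]
                        )
                        for si in range(4)
                    ],
                    axis=1,
                )
                die_crc = o * p_crc
                term = (die_crc * tcost[None, :]).sum(axis=1)
                cost_d[k_idx] += term * dfac
                cost_u[k_idx] += term
                dead_now = die_crc.sum(axis=1)
                crc_death[k_idx] += dead_now
                dead_crc[post] += dead_now
                survivors = o - die_crc
                dead_other[post] += survivors.sum(axis=1) * q_oc[post]
                occ[post] = survivors * (1.0 - q_oc[post, None])

            # age-100 cap: everyone still alive dies of other causes
            capped = a0 + t == MAX_AGE
            if capped.any():
                dead_other[capped] += occ[capped].sum(axis=1)
                occ[capped] = 0.0

            if record_mass:
                mass_history.append(occ.sum(axis=1) + dead_other + dead_crc)
            if not occ.sum() > 0:
                break

    # ---- IBD adjustment (scenario) ----
    if scenario.include_ibd and baseline_states.ibd.any():
        ibd_detected = diag.df["ibd_detected_usc"].to_numpy(dtype=bool)
        d_cost, d_qaly = ibd_lifecourse_adjustment(
            age0, sex_idx, baseline_states.ibd, ibd_detected, tables, rate
        )
        cost_d += d_cost
        qaly_d += d_qaly
        # undiscounted twins use rate 0 annuities
        d_cost0, d_qaly0 = ibd_lifecourse_adjustment(
            age0, sex_idx, baseline_states.ibd, ibd_detected, tables, 0.0
        )
        cost_u += d_cost0
        qaly_u += d_qaly0

    # ---- adenoma progression (scenario) ----
    if scenario.include_adenomas:
        adenoma = baseline_states.adenoma
        detected = diag.df["adenoma_detected"].to_numpy(dtype=bool)
        pending = (adenoma != "none") & ~detected & ~has_crc
        if pending.any():
            d_cost, d_qaly, d_ly, d_death = adenoma_lifecourse(
                age0[pending],
                sex_idx[pending],
                adenoma[pending],
                tables,
                rate,
                delay_model,
                adenoma_crc_extra_cost,
            )
            idx = np.where(pending)[0]
            cost_d[idx] += d_cost
            qaly_d[idx] += d_qaly
            ly_d[idx] += d_ly
            crc_death[idx] += d_death

    df = pd.DataFrame(
        {
            "person_id": pop.df["id"].to_numpy(),
            "discounted_cost": cost_d,
            "discounted_qaly": qaly_d,
            "discounted_ly": ly_d,
            "undiscounted_cost": cost_u,
            "undiscounted_qaly": qaly_u,
            "undiscounted_ly": ly_u,
            "crc_death_probability": crc_death,
            "stage_at_diagnosis": stage_dx,
        }
    )
    results = LifeCourseResults(df)
    if record_mass:
        return results, mass_history
    return results


def run_lifecourse(
    person,
    baseline_state,
    diag_outcome,
    tables: ModelTables,
    econ_cfg,
    scenario: ScenarioFlags = ScenarioFlags(),
    delay_model: DelayModel = DelayModel(),
) -> LifeCourseResult:
    """Single-person convenience wrapper around :func:`lifecourse_batch`."""
    from .disease import BaselineStates as _BS

    pop = Population.from_persons([person])
    bs = _BS(
        pd.DataFrame(
            {
                "person_id": [baseline_state.person_id],
                "crc_stage": [baseline_state.crc_stage],
                "adenoma": [baseline_state.adenoma],
                "ibd": [baseline_state.ibd],
            }
        )
    )
    d = diag_outcome
    diag = DiagnosticOutcomes(
        pd.DataFrame(
            {
                "person_id": [d.person_id],
                "referred": [d.referred],
                "attended": [d.attended],
                "investigation": [d.investigation],
                "crc_detected_usc": [d.crc_detected_usc],
                "crc_diagnosis_delay": [d.crc_diagnosis_delay],
                "adenoma_detected": [d.adenoma_detected],
                "ibd_detected_usc": [d.ibd_detected_usc],
                "ibd_diagnosis_delay": [d.ibd_diagnosis_delay],
                "short_term_cost": [d.short_term_cost],
                "short_term_qaly_loss": [d.short_term_qaly_loss],
                "delayed_dx_cost": [d.delayed_dx_cost],
            }
        )
    )
    res = lifecourse_batch(pop, bs, diag, tables, econ_cfg, scenario, delay_model)
    return res.records()[0]


# --------------------------------------------------------------------------
# IBD and adenoma adjustments
# --------------------------------------------------------------------------


def ibd_lifecourse_adjustment(
    age0, sex_idx, ibd_flags, ibd_detected, tables: ModelTables, rate: float
):
    """Per-person (cost delta, QALY delta) for the IBD disease course.

    Patients picked up at urgent referral follow the routine course; those
    whose diagnosis is delayed follow the complicated course (higher annual
    cost, lower utility multiplier), applied over their remaining expected
    lifetime via the life-table annuity.  Zero for non-IBD persons.
    """
    uc = tables.utility_cost
    n = len(np.asarray(age0))
    d_cost = np.zeros(n)
    d_qaly = np.zeros(n)
    flags = np.asarray(ibd_flags, dtype=bool)
    if not flags.any():
        return d_cost, d_qaly
    cells: dict[tuple[int, int], dict[str, float]] = {}
    for i in np.where(flags)[0]:
        key = (int(np.asarray(age0)[i]), int(np.asarray(sex_idx)[i]))
        if key not in cells:
            cells[key] = healthy_trace(key[0], key[1], tables.life, uc, rate)
        c = cells[key]
        course = "routine" if np.asarray(ibd_detected, dtype=bool)[i] else "complicated"
        d_cost[i] = uc.ibd_cost[course] * c["ly_d"]
        d_qaly[i] = (uc.ibd_utility_mult[course] - 1.0) * c["qaly_d"]
    return d_cost, d_qaly


def adenoma_conversion_trace(
    start_state: str,
    params: TransitionParams,
    horizon: int,
    survival: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cycle mass converting to CRC from an unresected adenoma.

    Expected-value recursion over {low-risk, high-risk} with annual
    probabilities (low->high, high->CRC); ``survival[t]`` (default 1) is the
    probability of being alive at the start of cycle t.  Returns an array of
    length ``horizon`` whose cumulative sum is the conversion probability —
    with no mortality and a high-risk start this is 1 - (1 - p)^T.
    """
    p_lh, p_hc = params.adenoma_progression
    low = 1.0 if start_state == "low_risk" else 0.0
    high = 1.0 if start_state == "high_risk" else 0.0
    if survival is None:
        survival = np.ones(horizon)
    conv = np.zeros(horizon)
    for t in range(horizon):
        conv[t] = survival[t] * high * p_hc
        high = high * (1.0 - p_hc) + low * p_lh
        low = low * (1.0 - p_lh)
    return conv


def adenoma_lifecourse(
    age0,
    sex_idx,
    adenoma_state,
    tables: ModelTables,
    rate: float,
    delay_model: DelayModel,
    extra_dx_cost: float = 0.0,
):
    """Lifetime deltas for *undetected* adenomas feeding later CRC incidence.

    Each year an unresected high-risk adenoma converts to stage-I CRC with
    the configured probability (low-risk first progress to high-risk); a
    conversion at year t contributes, discounted to baseline, the expected
    incremental (cost, QALY, LY, CRC death) of a symptomatic CRC case
    arising at that age and diagnosed after the mean delay, plus the
    delayed-diagnosis pathway cost.  Detected adenomas are resected and
    contribute nothing.
    """
    age0 = np.asarray(age0, dtype=int)
    sex_idx = np.asarray(sex_idx, dtype=int)
    n = len(age0)
    d_cost = np.zeros(n)
    d_qaly = np.zeros(n)
    d_ly = np.zeros(n)
    d_death = np.zeros(n)

    # expected incremental impact of CRC onset at (age, sex), cached
    impact_cache: dict[tuple[int, int], tuple[float, float, float, float]] = {}

    def crc_onset_impact(a: int, s: int) -> tuple[float, float, float, float]:
        key = (a, s)
        if key not in impact_cache:
            from .population import Person as _P
            from .disease import BaselineState as _B
            from .pathway import DiagnosticOutcome as _D

            person = _P(1, float(a), "M" if s else "F", 0.0, {}, True)
            base = _B(1, "I", "none", False)
            diag_case = _D(1, False, False, "none", False, delay_model.mean, False, False, 0.0, 0.0, 0.0)
            case = run_lifecourse(person, base, diag_case, tables, rate)
            healthy = healthy_trace(a, s, tables.life, tables.utility_cost, rate)
            impact_cache[key] = (
                case.discounted_cost + extra_dx_cost,
                case.discounted_qaly - healthy["qaly_d"],
                case.discounted_ly - healthy["ly_d"],
                case.crc_death_probability,
            )
        return impact_cache[key]

    surv_cache: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n):
        a, s = int(age0[i]), int(sex_idx[i])
        horizon = MAX_AGE - a
        if horizon <= 0:
            continue
        key = (a, s)
        if key not in surv_cache:
            sv = np.ones(horizon)
            alive = 1.0
            for t in range(horizon):
                sv[t] = alive
                alive *= 1.0 - float(tables.life.lookup(a + t, s))
            surv_cache[key] = sv
        conv = adenoma_conversion_trace(
            str(adenoma_state[i]), tables.transitions, horizon, surv_cache[key]
        )
        for t in np.nonzero(conv > 1e-12)[0]:
            c, qd, lyd, dd = crc_onset_impact(min(a + int(t), MAX_AGE), s)
            dfac = 1.0 / (1.0 + rate) ** t
            mass = conv[t]
            d_cost[i] += mass * c * dfac
            d_qaly[i] += mass * qd * dfac
            d_ly[i] += mass * lyd * dfac
            d_death[i] += mass * dd
    return d_cost, d_qaly, d_ly, d_death
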