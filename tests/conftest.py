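import numpy as np
import pandas as pd
import pytest

import crctriage as ct
from crctriage.disease import BaselineStates
from crctriage.markov import LifeTable, ModelTables, SurvivalTable, TransitionParams, UtilityCostTable


@pytest.fixture(scope="session")
def toy_cohort() -> ct.Population:
    return ct.make_toy_cohort()


@pytest.fixture(scope="session")
def small_population() -> ct.Population:
    cfg = ct.defaults.validation_population_config(n=5000, seed=11)
    return ct.generate_population(cfg)


@pytest.fixture(scope="session")
def default_tables() -> ModelTables:
    return ct.defaults.default_tables()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def fit_grid_spec() -> ct.MarginalSpec:
    # the four-point FIT grid used throughout the quantile-refit examples
    return ct.MarginalSpec(
        "fit", ((0.1, 0.0), (0.5, 2.0), (0.9, 40.0), (0.99, 300.0))
    )


def make_states(pop: ct.Population, crc=None, adenoma=None, ibd=None) -> BaselineStates:
    """Hand-build baseline states aligned with a population."""
    n = len(pop)
    return BaselineStates(
        pd.DataFrame(
            {
                "person_id": pop.df["id"].to_numpy(),
                "crc_stage": crc if crc is not None else ["none"] * n,
                "adenoma": adenoma if adenoma is not None else ["none"] * n,
                "ibd": ibd if ibd is not None else [False] * n,
            }
        )
    )


@pytest.fixture(scope="session")
def flat_tables() -> ModelTables:
    """Hand-set tables for exact arithmetic: constant utility 0.8, life-table
    hazard 0.1/yr, stage-independent CRC mortality pattern."""
    q = np.full((101, 2), 0.1)
    q[100] = 1.0
    probs = np.zeros((4, 2, 1, 10))
    probs[0] = 0.02
    probs[1] = 0.05
    probs[2] = 0.12
    probs[3] = 0.30
    uc = UtilityCostTable(
        gen_band_edges=(18.0,),
        gen_utility=((0.8, 0.8),),
        stage_utility_mult={"I": (0.9, 0.95), "II": (0.85, 0.9), "III": (0.7, 0.8), "IV": (0.5, 0.6)},
        stage_cost={"I": (1000.0, 100.0), "II": (2000.0, 200.0), "III": (3000.0, 300.0), "IV": (4000.0, 400.0)},
        terminal_cost={"I": 500.0, "II": 500.0, "III": 500.0, "IV": 500.0},
    )
    return ModelTables(
        transitions=TransitionParams(),
        survival=SurvivalTable((18.0,), probs),
        life=LifeTable(q),
        utility_cost=uc,
    )
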