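import dataclasses

import numpy as np
import pandas as pd
import pytest

from phenosel import (
    PhenotypeTable,
    default_config,
    simulate_experiment,
    standardize_traits,
)


def make_table(df: pd.DataFrame, levels=("complex", "simple")) -> PhenotypeTable:
    return PhenotypeTable(df, levels)


@pytest.fixture(scope="session")
def sim_default():
    """One realization of the reference 20x2x6 design (N = 240)."""
    return simulate_experiment(default_config(seed=11))


@pytest.fixture(scope="session")
def analysis_default(sim_default):
    table, _ = sim_default
    return standardize_traits(table, scope="pooled")


@pytest.fixture(scope="session")
def clean_config():
    """Default design without missingness or fitness noise floor effects:
    convenient for exact-identity tests."""
    cfg = default_config(seed=5)
    return dataclasses.replace(cfg, missingness=0.0, sigma_w=5.0)


@pytest.fixture()
def toy_df():
    rng = np.random.default_rng(0)
    n = 12
    return pd.DataFrame({
        "plant_id": [f"p{i}" for i in range(n)],
        "genotype": [f"L{i % 3}" for i in range(n)],
        "treatment": ["complex", "simple"] * (n // 2),
        "flowering_day": rng.uniform(30, 60, n),
        "size": rng.uniform(20, 70, n),
        "growth": rng.uniform(1, 6, n),
        "total_flowers": rng.integers(0, 120, n).astype(float),
    })
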