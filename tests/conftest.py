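import numpy as np
import pandas as pd
import pytest

from dftwin import SimulationConfig, simulate_pairs


@pytest.fixture
def small_pairs() -> pd.DataFrame:
    """Four hand-written pairs (2 MZ, 2 DZ) with one covariate."""
    return pd.DataFrame(
        {
            "pair_id": ["A", "A", "B", "B", "C", "C", "D", "D"],
            "twin_index": [1, 2] * 4,
            "zygosity": ["MZ", "MZ", "MZ", "MZ", "DZ", "DZ", "DZ", "DZ"],
            "outcome": [50.0, 30.0, 70.0, 50.0, 20.0, 60.0, 80.0, 40.0],
            "fast_food": [3.0, 1.0, 0.0, 0.0, 5.0, 2.0, 7.0, 7.0],
        }
    )


@pytest.fixture(scope="session")
def ace_sample() -> pd.DataFrame:
    """One medium ACE sample (h2=0.3, c2=0.4) on the latent scale."""
    cfg = SimulationConfig(
        n_mz_pairs=2000,
        n_dz_pairs=2000,
        h2=0.3,
        c2=0.4,
        e2=0.3,
        percentile_output=False,
        seed=20260927,
    )
    return simulate_pairs(cfg)


@pytest.fixture
def raw_survey() -> pd.DataFrame:
    """Small raw survey-item table, generated programmatically."""
    rng = np.random.default_rng(7)
    n = 40
    df = pd.DataFrame(
        {
            "pair_id": np.repeat([f"P{i}" for i in range(n // 2)], 2),
            "twin_index": np.tile([1, 2], n // 2),
            "fastfood_days": rng.integers(0, 8, n).astype(float),
            "breakfast_days": rng.integers(0, 8, n).astype(float),
            "lunch_days": rng.integers(0, 8, n).astype(float),
            "dinner_days": rng.integers(0, 8, n).astype(float),
            "sport_cat": rng.integers(0, 4, n).astype(float),
            "cycle_cat": rng.integers(0, 4, n).astype(float),
            "exercise_cat": rng.integers(0, 4, n).astype(float),
        }
    )
    for i in range(1, 13):
        df[f"veg_{i}"] = rng.integers(0, 2, n).astype(float)
    return df
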