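import numpy as np
import pandas as pd
import pytest

from itersurv.data_model import SurvivalDataset, infer_schema


@pytest.fixture
def toy_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ID": ["a", "b", "c", "d"],
            "STUDY": ["S1", "S1", "S2", "S2"],
            "TIME": [120.0, 300.0, 451.5, 80.0],
            "EVENT": [1, 0, 1, 1],
            "age": [61.0, 72.0, np.nan, 55.0],
            "ecog": ["E0", "E1", "E1", "E0"],
        }
    )


@pytest.fixture
def toy_dataset(toy_frame) -> SurvivalDataset:
    cov = toy_frame[["age", "ecog"]]
    return SurvivalDataset(toy_frame, infer_schema(cov))


def make_cohort_frame(n: int, seed: int, censor_frac: float = 0.4) -> pd.DataFrame:
    """Small single-study cohort with two informative covariates."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 2))
    t = np.exp(np.log(400.0) + 0.5 * x[:, 0] - 0.3 * x[:, 1] + 0.4 * rng.standard_normal(n))
    c = np.where(rng.random(n) < censor_frac, rng.uniform(100, 500, n), 1e9)
    obs = np.minimum(t, c)
    return pd.DataFrame(
        {
            "ID": [f"p{i}" for i in range(n)],
            "STUDY": "S1",
            "TIME": obs,
            "EVENT": (t <= c).astype(int),
            "x0": x[:, 0],
            "x1": x[:, 1],
        }
    )


@pytest.fixture
def small_cohort() -> SurvivalDataset:
    frame = make_cohort_frame(150, seed=7)
    return SurvivalDataset(frame, {"x0": "continuous", "x1": "continuous"})
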