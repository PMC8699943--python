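import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

import flindex as fx
from flindex.cohort import COLUMNS


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=4009), shared across tests."""
    return fx.generate_cohort(fx.default_config(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240614)


def make_cohort(**overrides) -> pd.DataFrame:
    """A tiny fully-populated cohort frame; columns overridable."""
    n = len(next(iter(overrides.values()))) if overrides else 4
    base = {
        "subject_id": [f"S{i}" for i in range(n)],
        "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
        "age": 50.0, "bmi": 24.0, "wc": 85.0, "sbp": 120.0, "dbp": 80.0,
        "fasting_glucose": 95.0, "tg": 100.0, "ast": 25.0, "alt": 25.0,
        "ggt": 30.0, "creatinine": 0.9, "alcohol": 5.0,
        "hbv_positive": False, "hcv_positive": False,
        "on_antihypertensives": False, "on_glucose_lowering": False,
        "us_steatosis": [True, False] * (n // 2) + [True] * (n % 2),
        "cap": 250.0, "lsm_median": 4.5, "lsm_iqr_over_median": 0.1,
        "lsm_n_valid": 10.0,
    }
    df = pd.DataFrame({k: (v if isinstance(v, (list, np.ndarray, pd.Series))
                           else [v] * n) for k, v in base.items()})
    for k, v in overrides.items():
        df[k] = v
    for col in ("hbv_positive", "hcv_positive", "on_antihypertensives",
                "on_glucose_lowering", "us_steatosis"):
        df[col] = df[col].astype("boolean")
    return df[list(COLUMNS)]


@pytest.fixture
def toy_cohort():
    return make_cohort()


def random_scores_labels(rng, n=60, prevalence=0.5, separation=1.0):
    """Random diagnostic data guaranteed to contain both classes."""
    labels = rng.random(n) < prevalence
    labels[0], labels[1] = True, False
    scores = rng.normal(0.0, 1.0, n) + separation * labels
    return scores, labels
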