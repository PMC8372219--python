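import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tabml import Dataset
from tabml.synth import SynthSpec, generate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def binary_df():
    """Tiny deterministic binary-outcome table with mixed feature types."""
    return pd.DataFrame(
        {
            "dx": ["healthy", "cancer", "healthy", "cancer", "healthy", "cancer"],
            "otu1": [0.1, 0.9, 0.2, 0.8, 0.15, 0.85],
            "otu2": [1.0, 1.1, 0.9, 1.2, 1.05, 0.95],
            "site": ["a", "a", "b", "b", "c", "c"],
        }
    )


@pytest.fixture
def binary_dataset(binary_df):
    return Dataset.from_dataframe(binary_df, outcome_name="dx")


@pytest.fixture
def planted_dataset():
    """n=200, p=10 continuous features, 5 informative at log-odds 2."""
    ds, truth = generate(
        SynthSpec(n_samples=200, n_continuous=10, n_informative=5,
                  effect_sizes=2.0, seed=42)
    )
    return ds, truth


def make_numeric_dataset(n=100, p=5, effect=1.0, n_informative=2, seed=0,
                         outcome_kind="binary", **kwargs):
    ds, truth = generate(
        SynthSpec(n_samples=n, n_continuous=p, n_informative=n_informative,
                  effect_sizes=effect, outcome_kind=outcome_kind, seed=seed, **kwargs)
    )
    return ds, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
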