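import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_counts_df():
    """Tiny genus count table: 4 samples x 5 taxa, fixed by hand."""
    return pd.DataFrame(
        [
            [10, 5, 0, 1, 1],
            [3, 8, 2, 0, 0],
            [1, 1, 12, 4, 2],
            [0, 2, 9, 6, 1],
        ],
        index=["F1", "F2", "F3", "F4"],
        columns=["g1", "g2", "g3", "g4", "g5"],
        dtype=float,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One spec-default synthetic dataset (n=8) shared across tests."""
    from fermcore import generate_dataset

    return generate_dataset(seed=11)


@pytest.fixture(scope="session")
def recovery_dataset():
    """The larger n=60 variant used for recovery-grade checks."""
    from fermcore import generate_dataset

    return generate_dataset(n_samples=60, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
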