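import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lncnet import synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """100-gene, one-module dataset with very strong memberships."""
    cfg = synthetic.SyntheticConfig(
        n_lncrna=40,
        n_mrna=60,
        n_modules=1,
        module_sizes=[50],
        membership_range=(0.95, 0.99),
        seed=7,
    )
    return synthetic.generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """One realization of the generator defaults (5 planted modules)."""
    return synthetic.generate_dataset(synthetic.SyntheticConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_expression():
    """Deterministic 6-gene x 6-sample matrix with two correlated pairs."""
    rng = np.random.default_rng(5)
    base = rng.normal(8, 1, size=(6, 6))
    base[1] = base[0] + rng.normal(0, 0.01, 6)   # near-duplicate of gene 0
    base[3] = -base[2] + 16                       # negation of gene 2
    return pd.DataFrame(
        base,
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(6)],
    )
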