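import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import genestab as gs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_study():
    """A compact study with blocks, subtypes and a clear outcome signal."""
    cfg = gs.SyntheticConfig(
        n_samples=60, n_genes=40, n_subtypes=2, block_sizes=(8, 8),
        within_block_rho=0.8, n_informative=10, effect_size=1.2,
        class_balance=0.4, seed=11,
    )
    return gs.generate_study(cfg)


@pytest.fixture(scope="session")
def small_split(small_study):
    return gs.train_test_split(
        small_study.expression, small_study.phenotypes, 40, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_expr(values, prefix_s="s", prefix_g="g"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return gs.ExpressionMatrix(
        values,
        [f"{prefix_s}{i}" for i in range(n)],
        [f"{prefix_g}{j}" for j in range(p)],
    )


def make_phen(y, **extra):
    import pandas as pd

    ids = [f"s{i}" for i in range(len(y))]
    kwargs = {k: pd.Series(v, index=ids) for k, v in extra.items()}
    return gs.PhenotypeTable(pd.Series(list(y), index=ids), **kwargs)
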