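import numpy as np
import pandas as pd
import pytest

from cernanet import SimulationParams
from cernanet.diffexpr import ExpressionMatrix


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A reduced synthetic study for fast unit tests."""
    return SimulationParams(
        n_lnc=60, n_mrna=120, n_mirna=15, hub_degree=10, n_hub_lnc=2, seed=11
    )


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams(seed=11)


def make_matrix(values, groups, biotypes=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a plain dict of gene -> sample values."""
    df = pd.DataFrame(values).T.astype(float)
    samples = list(df.columns)
    genes = list(df.index)
    if biotypes is None:
        biotypes = ["mRNA"] * len(genes)
    return ExpressionMatrix(
        values=df,
        groups=pd.Series(groups, index=samples),
        biotype=pd.Series(biotypes, index=genes),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
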