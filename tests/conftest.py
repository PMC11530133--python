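import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from apucnet import ExpressionMatrix, SimulationConfig

settings.register_profile("fixed", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("fixed")


def make_expr(values, unit="TPM", genes=None, samples=None) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(arr, index=genes, columns=samples), unit=unit
    )


@pytest.fixture
def rng():
    return np.random.default_rng(17)


@pytest.fixture
def random_tpm(rng):
    """12 genes × 20 samples of log-normal TPM-like values."""
    return make_expr(rng.lognormal(2.0, 1.0, size=(12, 20)))


@pytest.fixture
def staged_config():
    """Small planted-module config: 6 module genes + 24 background, no SHR/AR
    cross-structure, 300 samples per stage."""
    return SimulationConfig(
        n_genes=30,
        n_samples={"benign": 300, "primary": 300, "metastatic": 300},
        shr_genes=[],
        ar_genes=[],
        seed=5,
    )
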