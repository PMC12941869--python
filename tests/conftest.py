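import numpy as np
import pandas as pd
import pytest

from recurstrat import ExpressionMatrix, SimulationConfig, simulate_cohort


def make_matrix(values, genes=None, samples=None) -> ExpressionMatrix:
    """Build a validated ExpressionMatrix from a nested list / array."""
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def random_matrix(rng, n_genes=20, n_samples=6) -> ExpressionMatrix:
    return make_matrix(rng.normal(7, 2, size=(n_genes, n_samples)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort (5 normal / 154 primary / 13 recurrent)."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Default study design but fewer genes, for fast end-to-end tests."""
    cfg = SimulationConfig(
        n_genes=800,
        panel_sizes={name: 25 for name in SimulationConfig().panel_sizes},
        seed=7,
    )
    return simulate_cohort(cfg)
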