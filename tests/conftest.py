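import numpy as np
import pytest

from bgrmi.design import build_heterodimers
from bgrmi.io import ExpressionDataset
from bgrmi.simulate import SimulationConfig, make_irma_like_fixture, simulate


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    """3 genes x 6 time points, one series, deterministic values."""
    rng = np.random.default_rng(11)
    return ExpressionDataset(
        ["A", "B", "C"],
        [rng.uniform(0.1, 1.0, size=(3, 6))],
        [np.arange(6.0)],
    )


@pytest.fixture
def two_series_dataset() -> ExpressionDataset:
    rng = np.random.default_rng(5)
    return ExpressionDataset(
        ["A", "B", "C"],
        [rng.uniform(0, 1, size=(3, 4)), rng.uniform(0, 1, size=(3, 6))],
        [np.arange(4.0), np.arange(6.0)],
    )


@pytest.fixture(scope="session")
def sim_ten_genes():
    """Default-condition simulation: 10 genes, 5 series x 21 points."""
    ds, gold, true = simulate(SimulationConfig(seed=2024))
    return ds, gold, true


@pytest.fixture(scope="session")
def irma_fixture():
    return make_irma_like_fixture()


def driven_design(n=50, sigma=0.05, seed=0, n_candidates=4, driver=0, beta=1.0):
    """Target driven by exactly one candidate regulator, plus noise.

    Returns an ExpressionDataset whose gene 'T' follows
    T(t) = 0.2 + 0.3*T(t-1) + beta*R<driver>(t-1) + N(0, sigma^2),
    with the other candidates evolving independently.
    """
    rng = np.random.default_rng(seed)
    T = n + 1
    cand = rng.uniform(0.1, 1.0, size=(n_candidates, T))
    y = np.empty(T)
    y[0] = rng.uniform()
    for t in range(1, T):
        y[t] = 0.2 + 0.3 * y[t - 1] + beta * cand[driver, t - 1] + rng.normal(0, sigma)
    genes = ["T"] + [f"R{k}" for k in range(n_candidates)]
    ds = ExpressionDataset(genes, [np.vstack([y, cand])], [np.arange(T, dtype=float)])
    return ds, build_heterodimers(ds)
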