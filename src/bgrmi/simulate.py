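"""Synthetic time-course data from random sparse linear networks.

The generator samples a random directed graph at a requested density,
draws basal rates, self-decay and regulation coefficients, rescales
the full system matrix to spectral radius 0.9 so trajectories stay
bounded, and iterates the same linear lagged dynamics the inference
assumes:

    x_i(t) = alpha_i + beta_self,i * x_i(t-1)
             + sum_j beta_ij * x_j(t-1) + eps,   eps ~ N(0, sigma^2)

Initial states are uniform on (0, 1).  The gold standard contains the
off-diagonal edges only — self-decay is always present in the
dynamics but, mirroring community benchmark conventions, self-loops
are never scored.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionDataset, GoldStandard

__all__ = ["SimulationConfig", "simulate", "make_irma_like_fixture"]

SPECTRAL_RADIUS_TARGET = 0.9


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the 10-gene benchmark setting: five independent
    series of 21 time points, edge density 0.2, and measurement noise
    small relative to the O(1) expression range.
    """

    n_genes: int = 10
    n_series: int = 5
    timepoints_per_series: int = 21
    edge_density: float = 0.2
    coefficient_range: tuple[float, float] = (0.5, 1.5)
    self_decay_range: tuple[float, float] = (0.2, 0.8)
    basal_range: tuple[float, float] = (0.0, 0.5)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.edge_density < 1.0:
            raise ValueError("edge_density must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_genes < 2 or self.timepoints_per_series < 2 or self.n_series < 1:
            raise ValueError("need >= 2 genes, >= 2 time points, >= 1 series")
        for lo, hi in (self.coefficient_range, self.self_decay_range, self.basal_range):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError("ranges must be finite with lo <= hi")


def simulate(config: SimulationConfig) -> tuple[ExpressionDataset, GoldStandard, dict]:
    """Generate (dataset, gold standard, true parameters) from a config.

    The number of gold edges is floor(density * n * (n-1)), sampled
    uniformly among ordered off-diagonal pairs; coefficient signs are
    Rademacher.  ``true_parameters`` holds the post-rescaling system
    matrix ``W`` (diagonal = self-decay) and basal vector ``alpha``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_edges = int(np.floor(config.edge_density * n * (n - 1)))
    if n_edges == 0:
        raise ValueError("edge_density too low: zero edges requested")
    off_diag = [(i, j) for i in range(n) for j in range(n) if i != j]
    chosen = rng.choice(len(off_diag), size=n_edges, replace=False)
    gene_ids = [f"G{k + 1}" for k in range(n)]

    W = np.zeros((n, n))  # W[i, j]: effect of gene j on gene i
    for idx in chosen:
        i, j = off_diag[idx]
        mag = rng.uniform(*config.coefficient_range)
        W[i, j] = mag * rng.choice([-1.0, 1.0])
    W[np.diag_indices(n)] = rng.uniform(*config.self_decay_range, size=n)
    rho = max(abs(np.linalg.eigvals(W)))
    if rho > SPECTRAL_RADIUS_TARGET:
        W *= SPECTRAL_RADIUS_TARGET / rho
    alpha = rng.uniform(*config.basal_range, size=n)

    series, stamps = [], []
    T = config.timepoints_per_series
    for _ in range(config.n_series):
        x = np.empty((n, T))
        x[:, 0] = rng.uniform(0.0, 1.0, size=n)
        for t in range(1, T):
            noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
            x[:, t] = alpha + W @ x[:, t - 1] + noise
        series.append(x)
        stamps.append(np.arange(T, dtype=float))

    ds = ExpressionDataset(gene_ids, series, stamps)
    edges = {(gene_ids[j], gene_ids[i]) for idx in chosen for i, j in [off_diag[idx]]}
    gold = GoldStandard(edges, regulator_universe=set(gene_ids), target_universe=set(gene_ids))
    return ds, gold, {"W": W, "alpha": alpha}


# Fixed 5-gene, 6-edge loop with a feedback core, echoing the scale of
# the yeast synthetic benchmark circuit (5 genes, 6 interactions,
# switch-on/switch-off conditions).  Synthetic stand-in: topology and
# dynamics are generated here, not measured data.
_IRMA_LIKE_EDGES = [
    ("G1", "G2", 0.9),
    ("G2", "G3", 0.8),
    ("G3", "G4", 0.85),
    ("G4", "G5", 0.7),
    ("G5", "G1", -0.6),
    ("G2", "G5", 0.5),
]


def make_irma_like_fixture(
    noise_sd: float = 0.05,
    seed: int = 42,
    timepoints: int = 16,
) -> tuple[ExpressionDataset, GoldStandard]:
    """Fixed 5-gene, 6-edge network with two simulated conditions.

    Two series emulate switch-on / switch-off experiments: one starts
    from low expression with positive basal drive, the other from high
    expression with the drive removed.  Used for end-to-end pipeline
    tests without external downloads.
    """
    genes = [f"G{k}" for k in range(1, 6)]
    n = len(genes)
    W = np.zeros((n, n))
    for src, tgt, w in _IRMA_LIKE_EDGES:
        W[genes.index(tgt), genes.index(src)] = w
    W[np.diag_indices(n)] = 0.4
    rho = max(abs(np.linalg.eigvals(W)))
    if rho > SPECTRAL_RADIUS_TARGET:
        W *= SPECTRAL_RADIUS_TARGET / rho

    rng = np.random.default_rng(seed)
    series, stamps = [], []
    for alpha_level, x0_level in ((0.5, 0.05), (0.0, 1.0)):
        alpha = np.full(n, alpha_level)
        x = np.empty((n, timepoints))
        x[:, 0] = x0_level + rng.uniform(-0.02, 0.02, size=n)
        for t in range(1, timepoints):
            noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
            x[:, t] = alpha + W @ x[:, t - 1] + noise
        series.append(x)
        stamps.append(np.arange(timepoints, dtype=float))

    ds = ExpressionDataset(genes, series, stamps)
    gold = GoldStandard(
        {(src, tgt) for src, tgt, _ in _IRMA_LIKE_EDGES},
        regulator_universe=set(genes),
        target_universe=set(genes),
    )
    return ds, gold
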