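"""Model averaging: edge probabilities and signed interaction strengths.

The search returns, per gene, a list of accepted regulator subsets
with unnormalized posteriors.  The probability of an edge j -> i is
the normalized posterior mass of the accepted models that contain j;
the interaction strength beta_bar_ij is the posterior-weighted average
of j's maximum-likelihood coefficient across accepted models, with
models excluding j contributing exactly zero.  A positive strength
marks an activator, a negative one an inhibitor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .io import GoldStandard
from .scoring import GeneModelScore

__all__ = [
    "GRNResult",
    "average_strengths",
    "threshold_network",
    "DEFAULT_POSTERIOR_CUTOFF",
]

DEFAULT_POSTERIOR_CUTOFF = 0.75


@dataclass
class GRNResult:
    """Inferred network: posterior and strength matrices, targets x regulators."""

    gene_ids: list[str]
    regulator_ids: list[str]
    posterior: np.ndarray
    strength: np.ndarray
    accepted_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.posterior = np.asarray(self.posterior, dtype=float)
        self.strength = np.asarray(self.strength, dtype=float)
        shape = (len(self.gene_ids), len(self.regulator_ids))
        if self.posterior.shape != shape or self.strength.shape != shape:
            raise ValueError("matrix shapes do not match id lists")
        if np.any(self.posterior < 0) or np.any(self.posterior > 1):
            raise ValueError("edge posteriors must lie in [0, 1]")

    def edge_scores(self) -> dict[tuple[str, str], float]:
        """(regulator, target) -> posterior map over nonzero entries."""
        out = {}
        for i, tgt in enumerate(self.gene_ids):
            for j, reg in enumerate(self.regulator_ids):
                if self.posterior[i, j] > 0:
                    out[(reg, tgt)] = float(self.posterior[i, j])
        return out


def model_weights(accepted: list[GeneModelScore]) -> np.ndarray:
    """Normalized posterior weights of the accepted models (log-sum-exp)."""
    if not accepted:
        return np.empty(0)
    lp = np.array([m.log_posterior_unnorm for m in accepted])
    return np.exp(lp - logsumexp(lp))


def average_strengths(
    accepted: list[GeneModelScore],
    regulator_ids: list[str],
) -> np.ndarray:
    """Posterior-weighted average coefficient per regulator (zero-padded).

    Models that exclude a regulator contribute 0 to its average, so
    the strength shrinks toward zero as the including models' total
    weight shrinks.
    """
    row = np.zeros(len(regulator_ids))
    if not accepted:
        return row
    w = model_weights(accepted)
    for wk, m in zip(w, accepted):
        for rid in m.regulator_subset:
            row[regulator_ids.index(rid)] += wk * m.coefficient(rid)
    return row


def threshold_network(
    result: GRNResult,
    cutoff: float = DEFAULT_POSTERIOR_CUTOFF,
) -> tuple[GoldStandard, dict[tuple[str, str], str]]:
    """Keep edges with posterior strictly above ``cutoff``; attach signs.

    Returns the retained edge set plus a sign map: "activator" where
    the averaged strength is positive, "inhibitor" where negative,
    "ambiguous" on exact cancellation.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    edges: set[tuple[str, str]] = set()
    signs: dict[tuple[str, str], str] = {}
    for i, tgt in enumerate(result.gene_ids):
        for j, reg in enumerate(result.regulator_ids):
            if result.posterior[i, j] > cutoff:
                edges.add((reg, tgt))
                b = result.strength[i, j]
                signs[(reg, tgt)] = (
                    "activator" if b > 0 else ("inhibitor" if b < 0 else "ambiguous")
                )
    gs = GoldStandard(
        edges,
        regulator_universe=set(result.regulator_ids),
        target_universe=set(result.gene_ids),
        allow_self=True,
    )
    return gs, signs
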