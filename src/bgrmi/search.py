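"""Greedy branch-and-bound search over regulator subsets.

For each target gene the search scores the null model (intercept +
self-lag only) and uses its unnormalized log posterior as the initial
acceptance threshold.  Stage by stage, every queued subset is scored;
subsets beating the threshold are accepted, their posterior mass is
accumulated into a normalization constant and into each member
regulator's edge accumulator, and the stage's best accepted posterior
becomes the next threshold (stagewise mode, the default — in fixed
mode the null-model threshold is kept throughout).  The next queue is
the set of one-regulator extensions of the stage's accepted subsets,
deduplicated globally, capped at a maximum model size.  The search
stops when a stage accepts nothing.  Edge posteriors are the
accumulated mass divided by the normalization constant; the null
model's mass is not part of the constant, so posteriors are
conditional on at least one regulator being present.

All accumulation happens in natural-log space via log-sum-exp; the
search contains no randomness, so identical inputs give bit-identical
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import logsumexp

from .averaging import GRNResult, average_strengths
from .design import RegulatorSet, RegressionDesign, build_design
from .io import ExpressionDataset
from .priors import PriorMatrix, chip_log_prior, sparsity_log_prior
from .scoring import GeneModelScore, score_model, zellner_g

__all__ = ["SearchConfig", "search_gene", "extend_subsets", "infer_network"]

logger = logging.getLogger(__name__)

Subset = tuple[str, ...]


@dataclass
class SearchConfig:
    """Tunable knobs of the per-gene model search.

    max_model_size : largest regulator count explored; ``None`` means
        min(10, n - 4), keeping n > p + 2 for every admissible fit.
    threshold_mode : "stagewise" raises the cutoff to the best accepted
        posterior each stage; "fixed" keeps the null model's posterior
        as the cutoff for the whole search.
    g : Zellner prior-covariance multiplier; ``None`` selects the
        benchmark max(n, p_total^2).
    lag : regulator-to-target delay in sampling steps.
    """

    max_model_size: int | None = None
    threshold_mode: str = "stagewise"
    g: float | None = None
    lag: int = 1

    def __post_init__(self) -> None:
        if self.threshold_mode not in {"stagewise", "fixed"}:
            raise ValueError("threshold_mode must be 'stagewise' or 'fixed'")
        if self.max_model_size is not None and self.max_model_size < 1:
            raise ValueError("max_model_size must be >= 1")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")

    def resolved_max_size(self, n: int) -> int:
        if self.max_model_size is not None:
            return self.max_model_size
        return max(1, min(10, n - 4))


def extend_subsets(
    accepted: list[Subset],
    universe: list[str],
    max_model_size: int | None = None,
) -> set[Subset]:
    """All one-regulator extensions of the accepted subsets, deduplicated.

    Subsets are canonicalized as sorted tuples, so the same extension
    reached from different parents is emitted once.  Extensions beyond
    ``max_model_size`` are dropped.
    """
    out: set[Subset] = set()
    for subset in accepted:
        if max_model_size is not None and len(subset) >= max_model_size:
            continue
        have = set(subset)
        for rid in universe:
            if rid not in have:
                out.add(tuple(sorted(have | {rid})))
    return out


def search_gene(
    design: RegressionDesign,
    prior_fn: Callable[[Subset], float],
    config: SearchConfig,
) -> tuple[dict[str, float], list[GeneModelScore]]:
    """Run the greedy search for one target gene.

    Returns the per-regulator edge posteriors and the full list of
    accepted models (across all stages), in acceptance order.
    """
    max_size = config.resolved_max_size(design.n)
    g = config.g if config.g is not None else zellner_g(design.n, max(1, len(design.candidate_ids)))

    null = score_model(design, (), g, prior_fn(()))
    threshold = null.log_posterior_unnorm
    queue: set[Subset] = {(rid,) for rid in design.candidate_ids}
    evaluated: set[Subset] = {()}
    accepted_all: list[GeneModelScore] = []
    edge_logmass: dict[str, list[float]] = {}
    stage = 0

    while queue:
        stage += 1
        stage_accepted: list[GeneModelScore] = []
        for subset in sorted(queue):
            evaluated.add(subset)
            m = score_model(design, subset, g, prior_fn(subset))
            if not np.isfinite(m.log_posterior_unnorm):
                logger.debug("%s: singular subset %s skipped", design.target_id, subset)
                continue
            if m.log_posterior_unnorm > threshold:
                stage_accepted.append(m)
        if not stage_accepted:
            break
        accepted_all.extend(stage_accepted)
        for m in stage_accepted:
            for rid in m.regulator_subset:
                edge_logmass.setdefault(rid, []).append(m.log_posterior_unnorm)
        if config.threshold_mode == "stagewise":
            threshold = max(m.log_posterior_unnorm for m in stage_accepted)
        queue = extend_subsets(
            [m.regulator_subset for m in stage_accepted],
            design.candidate_ids,
            max_model_size=max_size,
        ) - evaluated
        logger.debug(
            "%s stage %d: accepted %d, queue %d", design.target_id, stage, len(stage_accepted), len(queue)
        )

    posteriors = {rid: 0.0 for rid in design.candidate_ids}
    if accepted_all:
        nc = float(logsumexp([m.log_posterior_unnorm for m in accepted_all]))
        for rid, masses in edge_logmass.items():
            # mass of models containing rid can only round up past NC
            posteriors[rid] = min(1.0, float(np.exp(logsumexp(masses) - nc)))
    else:
        logger.warning("%s: no model beat the null; all edge posteriors 0", design.target_id)
    return posteriors, accepted_all


def make_prior_fn(
    target: str,
    candidate_ids: list[str],
    prior: PriorMatrix | None,
    components: dict[str, tuple[str, str]] | None = None,
) -> Callable[[Subset], float]:
    """Structure-prior callable for one gene: sparsity-only, or
    binding-evidence Bernoulli terms plus sparsity when a PriorMatrix
    is supplied."""
    if prior is None:
        return lambda subset: sparsity_log_prior(len(subset))
    return lambda subset: chip_log_prior(target, subset, prior, candidate_ids, components)


def infer_network(
    ds: ExpressionDataset,
    regs: RegulatorSet,
    prior: PriorMatrix | None = None,
    config: SearchConfig | None = None,
) -> GRNResult:
    """Infer the full network: one independent search per target gene.

    Per-gene failures are isolated (the gene's row stays zero and the
    error is logged); results do not depend on gene order.
    """
    config = config or SearchConfig()
    posterior = np.zeros((ds.n_genes, len(regs.regulator_ids)))
    strength = np.zeros_like(posterior)
    counts: dict[str, int] = {}
    for i, target in enumerate(ds.gene_ids):
        try:
            design = build_design(ds, regs, target, lag=config.lag)
            prior_fn = make_prior_fn(target, design.candidate_ids, prior, regs.components)
            edge_post, accepted = search_gene(design, prior_fn, config)
        except Exception:
            logger.exception("inference failed for gene %s; row left empty", target)
            counts[target] = 0
            continue
        counts[target] = len(accepted)
        for rid, p in edge_post.items():
            posterior[i, regs.regulator_ids.index(rid)] = p
        strength[i] = average_strengths(accepted, regs.regulator_ids)
    return GRNResult(list(ds.gene_ids), list(regs.regulator_ids), posterior, strength, counts)
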