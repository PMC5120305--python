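"""Structure priors over regulator subsets.

Two priors are offered.  The default sparsity prior penalizes model
size with the power law p(M_k) = L^-2.66, L being the number of
regulators in the model.  The ChIP-seq-informed prior additionally
scores each candidate TF's membership as an independent Bernoulli
event with probability P_ij = Q_ij * R: Q_ij is a tiered
binding-evidence weight (1 for interactions in the filtered proximal
consensus network, 0.5 for those only in the unfiltered proximal or
distal networks, 0.05 for interactions absent from all three), and R
is the cross-cell-type binding reproducibility (default 0.26, the
value estimated from the TF with the deepest ChIP-seq coverage and
applied globally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PeakSet

__all__ = [
    "PriorMatrix",
    "SPARSITY_EXPONENT",
    "DEFAULT_R_GLOBAL",
    "TIER_WEIGHTS",
    "sparsity_log_prior",
    "build_chip_prior",
    "chip_log_prior",
    "estimate_peak_reproducibility",
    "read_tier_file",
    "read_prior_tsv",
]

SPARSITY_EXPONENT = 2.66
DEFAULT_R_GLOBAL = 0.26
TIER_WEIGHTS = {"proximal_filtered": 1.0, "unfiltered_or_distal": 0.5, "absent": 0.05}
_CLAMP_EPS = 1e-6


def sparsity_log_prior(L: int) -> float:
    """Log of the power-law sparsity prior p(M_k) = L^-2.66.

    The regulator-free null model is treated as L = 1 so its prior is
    finite (the search needs a finite null-model threshold).
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    return 0.0 if L <= 1 else -SPARSITY_EXPONENT * float(np.log(L))


@dataclass
class PriorMatrix:
    """Per TF-gene binding probabilities P_ij on a targets x regulators grid."""

    targets: list[str]
    regulators: list[str]
    values: np.ndarray
    q_tier: np.ndarray | None = None
    r_global: float = DEFAULT_R_GLOBAL
    _t_index: dict = field(init=False, repr=False)
    _r_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.targets), len(self.regulators)):
            raise ValueError("values shape does not match target/regulator lists")
        if np.any(self.values <= 0.0) or np.any(self.values >= 1.0):
            raise ValueError("P_ij must lie strictly inside (0, 1)")
        self._t_index = {t: i for i, t in enumerate(self.targets)}
        self._r_index = {r: j for j, r in enumerate(self.regulators)}

    def prob(self, target: str, regulator: str, components: tuple[str, ...] | None = None) -> float:
        """P_ij for one pair; a heterodimer's probability is the product
        of its components' (independence assumption)."""
        monomers = components if components and len(components) > 1 else (regulator,)
        p = 1.0
        for m in monomers:
            p *= self.values[self._t_index[target], self._r_index[m]]
        return float(np.clip(p, _CLAMP_EPS, 1.0 - _CLAMP_EPS))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.targets, columns=self.regulators)


def build_chip_prior(
    tier_assignments: dict[tuple[str, str], str],
    r: float = DEFAULT_R_GLOBAL,
    targets: list[str] | None = None,
    regulators: list[str] | None = None,
) -> PriorMatrix:
    """Build P_ij = Q_ij * r from tiered consensus-network annotations.

    Pairs missing from ``tier_assignments`` default to the "absent"
    tier.  Values are clamped into [1e-6, 1 - 1e-6] so no membership
    event has log probability -inf.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError("r must be in (0, 1]")
    for pair, tier in tier_assignments.items():
        if tier not in TIER_WEIGHTS:
            raise ValueError(f"unknown tier {tier!r} for pair {pair}")
    if targets is None:
        targets = sorted({t for t, _ in tier_assignments})
    if regulators is None:
        regulators = sorted({j for _, j in tier_assignments})
    vals = np.empty((len(targets), len(regulators)))
    for i, t in enumerate(targets):
        for j, reg in enumerate(regulators):
            q = TIER_WEIGHTS[tier_assignments.get((t, reg), "absent")]
            vals[i, j] = np.clip(q * r, _CLAMP_EPS, 1.0 - _CLAMP_EPS)
    return PriorMatrix(list(targets), list(regulators), vals, r_global=r)


def chip_log_prior(
    target: str,
    subset: tuple[str, ...],
    prior: PriorMatrix,
    candidate_ids: list[str],
    components: dict[str, tuple[str, str]] | None = None,
) -> float:
    """Log structure prior of a subset under the binding-evidence model.

    Each candidate regulator contributes an independent Bernoulli term
    — log P_ij if it is in the subset, log(1 - P_ij) otherwise — and
    the power-law model-size term is added on top.  Heterodimer
    candidates use the product of their components' P_ij.
    """
    components = components or {}
    in_subset = set(subset)
    total = 0.0
    for rid in candidate_ids:
        p = prior.prob(target, rid, components.get(rid))
        total += np.log(p) if rid in in_subset else np.log1p(-p)
    return float(total + sparsity_log_prior(len(subset)))


def estimate_peak_reproducibility(peaksets: list[PeakSet]) -> float:
    """Cross-dataset binding reproducibility of one TF from peak files.

    All intervals across the K datasets are union-merged (>= 1 bp
    overlap) into consensus regions; each region's support is the
    number of datasets overlapping it.  The estimate is the mean of
    (support - 1) / (K - 1) over consensus regions: 1 when every
    dataset hits every region, 0 (clamped to 1e-6) when no region is
    seen twice.
    """
    K = len(peaksets)
    if K < 2:
        raise ValueError("reproducibility undefined for fewer than 2 peak sets")
    tagged = []  # (chrom, start, end, dataset index)
    for d, ps in enumerate(peaksets):
        for chrom, start, end in ps.intervals:
            tagged.append((chrom, start, end, d))
    if not tagged:
        raise ValueError("no intervals in any peak set")
    tagged.sort()
    fracs: list[float] = []
    cur_chrom, cur_start, cur_end = tagged[0][0], tagged[0][1], tagged[0][2]
    cur_sets = {tagged[0][3]}
    for chrom, start, end, d in tagged[1:]:
        if chrom == cur_chrom and start < cur_end:  # >= 1 bp overlap merges
            cur_end = max(cur_end, end)
            cur_sets.add(d)
        else:
            fracs.append((len(cur_sets) - 1) / (K - 1))
            cur_chrom, cur_start, cur_end, cur_sets = chrom, start, end, {d}
    fracs.append((len(cur_sets) - 1) / (K - 1))
    return float(np.clip(np.mean(fracs), _CLAMP_EPS, 1.0))


def read_tier_file(path: str) -> dict[tuple[str, str], str]:
    """Load a 3-column TSV (target, TF, tier) of consensus annotations."""
    out: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip() or ln.startswith("#"):
                continue
            cells = ln.rstrip("\n").split("\t")
            if len(cells) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            if cells[2] not in TIER_WEIGHTS:
                raise ValueError(f"{path}:{lineno}: unknown tier {cells[2]!r}")
            out[(cells[0], cells[1])] = cells[2]
    return out


def read_prior_tsv(path: str, r_global: float = DEFAULT_R_GLOBAL) -> PriorMatrix:
    """Load a targets x regulators probability matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = np.clip(df.to_numpy(dtype=float), _CLAMP_EPS, 1.0 - _CLAMP_EPS)
    return PriorMatrix(
        [str(t) for t in df.index], [str(r) for r in df.columns], vals, r_global=r_global
    )
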