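"""Lagged regression designs from time-course data.

Gene expression at time t is modelled as a linear function of the
gene's own expression and of candidate-regulator expressions one
sampling step earlier:

    x_i(t) = alpha_i + beta_self * x_i(t-1) + sum_j beta_ij * r_j(t-1) + eps

Rows of the design never span series boundaries.  The lag is counted
in sampling steps, not physical time: the discretization absorbs the
interval length into the coefficients.  Candidate regulators may be
single TFs or TF-TF heterodimers, whose activity proxy is the
elementwise product of the partners' mRNA levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionDataset

__all__ = [
    "RegulatorSet",
    "RegressionDesign",
    "aggregate_isoforms",
    "build_heterodimers",
    "build_design",
    "HETERODIMER_SEP",
]

HETERODIMER_SEP = ":"


@dataclass
class RegulatorSet:
    """Candidate regulators (monomer TFs plus optional heterodimers).

    ``expression_rows`` holds one regulators x time matrix per series,
    aligned with the originating dataset; a heterodimer row equals the
    elementwise product of its component rows.
    """

    regulator_ids: list[str]
    expression_rows: list[np.ndarray]
    components: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.regulator_ids)) != len(self.regulator_ids):
            raise ValueError("duplicate regulator ids")
        self.expression_rows = [np.asarray(m, dtype=float) for m in self.expression_rows]
        for m in self.expression_rows:
            if m.shape[0] != len(self.regulator_ids):
                raise ValueError("expression_rows shape mismatch")

    def row(self, rid: str) -> int:
        return self.regulator_ids.index(rid)

    def monomers_of(self, rid: str) -> tuple[str, ...]:
        """Monomer ids behind a regulator id (itself, or its two partners)."""
        return self.components.get(rid, (rid,))


@dataclass
class RegressionDesign:
    """One target gene's lagged least-squares problem.

    ``X_base`` carries the intercept and self-lag columns, in that
    order; ``X_candidates`` carries one lagged column per candidate
    regulator in ``candidate_ids``.
    """

    target_id: str
    y: np.ndarray
    X_base: np.ndarray
    X_candidates: np.ndarray
    candidate_ids: list[str]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def columns_for(self, subset: tuple[str, ...]) -> np.ndarray:
        """Design matrix [intercept, self-lag, subset columns]."""
        idx = [self.candidate_ids.index(s) for s in subset]
        return np.hstack([self.X_base, self.X_candidates[:, idx]])


def aggregate_isoforms(ds: ExpressionDataset, gene_map: dict[str, str]) -> ExpressionDataset:
    """Sum isoform rows sharing a gene symbol into one row per gene.

    Intended for CAGE-style data where several transcription start
    sites of one gene are quantified separately; expression of a gene
    is the sum of its isoforms' normalized counts per sample.
    """
    missing = [g for g in ds.gene_ids if g not in gene_map]
    if missing:
        raise KeyError(f"unmapped isoform ids: {missing}")
    symbols: list[str] = []
    for iso in ds.gene_ids:
        sym = gene_map[iso]
        if sym not in symbols:
            symbols.append(sym)
    new_series = []
    for mat in ds.series:
        out = np.zeros((len(symbols), mat.shape[1]))
        for i, iso in enumerate(ds.gene_ids):
            out[symbols.index(gene_map[iso])] += mat[i]
        new_series.append(out)
    return ExpressionDataset(symbols, new_series, ds.time_stamps, scale_tag=ds.scale_tag)


def build_heterodimers(
    ds: ExpressionDataset,
    pairs: list[tuple[str, str]] = (),
    regulator_ids: list[str] | None = None,
) -> RegulatorSet:
    """Assemble the candidate-regulator set, adding heterodimer rows.

    Each (j, l) pair contributes a pseudo-regulator ``j:l`` whose
    expression is the elementwise product of the partners' rows,
    computed per series on the data's loaded scale.  Monomers are
    retained.  ``regulator_ids`` restricts the monomer candidates (e.g.
    a known-TF list); by default every gene is a candidate.
    """
    monomers = list(regulator_ids) if regulator_ids is not None else list(ds.gene_ids)
    for rid in monomers:
        if rid not in ds.gene_ids:
            raise KeyError(f"unknown regulator id: {rid!r}")
    ids = list(monomers)
    components: dict[str, tuple[str, str]] = {}
    for j, l in pairs:
        if j == l:
            raise ValueError(f"self-dimerization ({j}, {j}) is not modelled")
        for rid in (j, l):
            if rid not in ds.gene_ids:
                raise KeyError(f"unknown heterodimer component: {rid!r}")
        a, b = sorted((j, l))
        hid = f"{a}{HETERODIMER_SEP}{b}"
        if hid in components:
            continue
        ids.append(hid)
        components[hid] = (a, b)
    rows = []
    for mat in ds.series:
        out = np.empty((len(ids), mat.shape[1]))
        for k, rid in enumerate(ids):
            if rid in components:
                a, b = components[rid]
                out[k] = mat[ds.row(a)] * mat[ds.row(b)]
            else:
                out[k] = mat[ds.row(rid)]
        rows.append(out)
    return RegulatorSet(ids, rows, components)


def build_design(
    ds: ExpressionDataset,
    regs: RegulatorSet,
    target: str,
    lag: int = 1,
) -> RegressionDesign:
    """Build the lagged design for one target gene.

    For each series s and each time index t in [lag, T_s): one row with
    response = target at t, self-lag = target at t-lag, and candidate
    columns = regulator expressions at t-lag.  The target's own monomer
    id — and any heterodimer containing it — is excluded from the
    candidates (self-regulation is always carried by the self-lag
    column instead).
    """
    if lag < 1:
        raise ValueError("lag must be a positive number of sampling steps")
    ti = ds.row(target)
    keep = [
        k for k, rid in enumerate(regs.regulator_ids)
        if target not in regs.monomers_of(rid)
    ]
    candidate_ids = [regs.regulator_ids[k] for k in keep]
    ys, selfs, cands = [], [], []
    for mat, rmat in zip(ds.series, regs.expression_rows):
        T = mat.shape[1]
        if T <= lag:
            raise ValueError(
                f"series with {T} time points is too short for lag {lag}"
            )
        ys.append(mat[ti, lag:])
        selfs.append(mat[ti, : T - lag])
        cands.append(rmat[np.ix_(keep, np.arange(T - lag))].T)
    y = np.concatenate(ys)
    self_lag = np.concatenate(selfs)
    X_base = np.column_stack([np.ones_like(y), self_lag])
    X_candidates = np.vstack(cands) if cands else np.empty((y.shape[0], 0))
    return RegressionDesign(target, y, X_base, X_candidates, candidate_ids)
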