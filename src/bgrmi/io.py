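"""Readers and writers for the formats the tool touches.

Expression matrices are plain TSV with genes in rows and samples in
columns; multi-series experiments are supplied either as several files
(one per series) or as a single block-separated file in the DREAM4
time-series dialect (first column ``Time``, one column per gene, one
block per perturbation series).  Interval inputs are BED3 with 0-based
half-open coordinates.  Gold standards are 2- or 3-column edge lists.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GoldStandard",
    "PeakSet",
    "FormatError",
    "read_expression_tsv",
    "read_dream4_timeseries",
    "read_edge_list",
    "read_bed",
    "write_grn",
    "read_grn",
    "write_gold_standard",
    "write_expression_tsv",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class ExpressionDataset:
    """Multi-series time-course expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per matrix row.
    series : list of ndarray
        One ``(len(gene_ids), T_s)`` matrix per independent time series.
    time_stamps : list of ndarray
        Per-series sampling times, strictly increasing.
    scale_tag : {"linear", "log2"}
        Provenance marker for the measurement scale; values are used
        as loaded and never transformed.
    """

    gene_ids: list[str]
    series: list[np.ndarray]
    time_stamps: list[np.ndarray]
    scale_tag: str = "linear"

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.series = [np.asarray(s, dtype=float) for s in self.series]
        self.time_stamps = [np.asarray(t, dtype=float) for t in self.time_stamps]
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise FormatError(f"duplicate gene id: {g!r}")
            seen.add(g)
        if len(self.series) != len(self.time_stamps):
            raise FormatError("series / time_stamps length mismatch")
        if not self.series:
            raise FormatError("dataset has no series")
        for k, (mat, ts) in enumerate(zip(self.series, self.time_stamps)):
            if mat.ndim != 2 or mat.shape[0] != len(self.gene_ids):
                raise FormatError(
                    f"series {k}: expected {len(self.gene_ids)} rows, got shape {mat.shape}"
                )
            if mat.shape[1] != ts.shape[0]:
                raise FormatError(f"series {k}: {mat.shape[1]} columns vs {ts.shape[0]} time stamps")
            if ts.shape[0] < 2:
                raise FormatError(f"series {k}: needs >= 2 time points")
            if not np.all(np.diff(ts) > 0):
                raise FormatError(f"series {k}: time stamps not strictly increasing")
            if np.isnan(mat).any():
                raise FormatError(f"series {k}: contains NaN (impute upstream; no missing-data model)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_series(self) -> int:
        return len(self.series)

    def row(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene_id!r}") from None


@dataclass
class GoldStandard:
    """Reference edge set for benchmarking.

    ``edges`` holds directed (regulator, target) pairs; the two
    universes define every scoreable pair.
    """

    edges: set[tuple[str, str]]
    regulator_universe: set[str] = field(default_factory=set)
    target_universe: set[str] = field(default_factory=set)
    allow_self: bool = False

    def __post_init__(self) -> None:
        self.edges = set(self.edges)
        if not self.regulator_universe:
            self.regulator_universe = {r for r, _ in self.edges}
        if not self.target_universe:
            self.target_universe = {t for _, t in self.edges}
        self.regulator_universe = set(self.regulator_universe)
        self.target_universe = set(self.target_universe)
        for r, t in self.edges:
            if r not in self.regulator_universe or t not in self.target_universe:
                raise FormatError(f"edge ({r}, {t}) outside declared universes")
            if r == t and not self.allow_self:
                raise FormatError(f"self-pair ({r}, {t}) not allowed")

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class PeakSet:
    """Sorted genomic intervals from one ChIP-seq dataset (0-based, half-open)."""

    intervals: list[tuple[str, int, int]]
    source_label: str = ""

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise FormatError(f"interval {chrom}:{start}-{end} has start >= end")
        self.intervals = sorted(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_expression_tsv(
    paths: str | list[str],
    scale_tag: str = "linear",
) -> ExpressionDataset:
    """Load one or more genes-in-rows TSV files, one series per file.

    The header row carries sample labels; if every label parses as a
    number the labels are used as time stamps, otherwise stamps default
    to 0, 1, 2, ...  All files must list the same genes in the same
    order.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    gene_ids: list[str] | None = None
    series: list[np.ndarray] = []
    stamps: list[np.ndarray] = []
    for path in paths:
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        ids = [str(g) for g in df.index]
        dup = {g for g in ids if ids.count(g) > 1}
        if dup:
            raise FormatError(f"{path}: duplicate gene ids: {sorted(dup)}")
        if gene_ids is None:
            gene_ids = ids
        elif ids != gene_ids:
            raise FormatError(f"{path}: gene rows differ from first file")
        mat = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        if np.isnan(mat).any():
            r, c = np.argwhere(np.isnan(mat))[0]
            raise FormatError(
                f"{path}: non-numeric or missing cell at gene {ids[r]!r}, column {df.columns[c]!r}"
            )
        try:
            ts = np.asarray([float(c) for c in df.columns])
        except ValueError:
            ts = np.arange(mat.shape[1], dtype=float)
        if not np.all(np.diff(ts) > 0):
            raise FormatError(f"{path}: time stamps not strictly increasing")
        series.append(mat)
        stamps.append(ts)
    assert gene_ids is not None
    return ExpressionDataset(gene_ids, series, stamps, scale_tag=scale_tag)


def read_dream4_timeseries(path: str, scale_tag: str = "linear") -> ExpressionDataset:
    """Load a DREAM4-dialect time-series file.

    The file has a header ``Time<TAB>G1<TAB>...``, one row per sampled
    time point, and one block per series.  Blocks are separated by
    blank lines; a row whose time stamp does not exceed its
    predecessor's also starts a new block (the published files restart
    at Time=0).  Genes are transposed to rows.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    header: list[str] | None = None
    blocks: list[list[list[float]]] = []
    current: list[list[float]] = []
    for lineno, ln in enumerate(lines, start=1):
        if not ln.strip():
            if current:
                blocks.append(current)
                current = []
            continue
        cells = ln.split("\t")
        if header is None:
            if cells[0].strip().lower() != "time":
                raise FormatError(f"{path}: first column must be 'Time', got {cells[0]!r}")
            header = [c.strip().strip('"') for c in cells]
            continue
        if len(cells) != len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}")
        try:
            row = [float(c) for c in cells]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed numeric cell ({exc})") from exc
        if current and row[0] <= current[-1][0]:
            blocks.append(current)
            current = []
        current.append(row)
    if current:
        blocks.append(current)
    if header is None or not blocks:
        raise FormatError(f"{path}: no data rows")
    gene_ids = header[1:]
    series, stamps = [], []
    for block in blocks:
        arr = np.asarray(block, dtype=float)
        stamps.append(arr[:, 0])
        series.append(arr[:, 1:].T)
    return ExpressionDataset(gene_ids, series, stamps, scale_tag=scale_tag)


def read_edge_list(
    path: str,
    regulator_universe: set[str] | None = None,
    target_universe: set[str] | None = None,
) -> GoldStandard:
    """Load a 2-column (all positives) or 3-column (labelled) edge list."""
    edges: set[tuple[str, str]] = set()
    regs: set[str] = set(regulator_universe or ())
    tgts: set[str] = set(target_universe or ())
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip() or ln.startswith("#"):
                continue
            cells = ln.rstrip("\n").split("\t")
            if len(cells) == 2:
                reg, tgt, label = cells[0], cells[1], "1"
            elif len(cells) >= 3:
                reg, tgt, label = cells[0], cells[1], cells[2].strip()
            else:
                raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns")
            if label not in {"0", "1"}:
                raise FormatError(f"{path}:{lineno}: label must be 0 or 1, got {label!r}")
            regs.add(reg)
            tgts.add(tgt)
            if label == "1":
                edges.add((reg, tgt))
    return GoldStandard(edges, regulator_universe=regs, target_universe=tgts)


def read_bed(path: str, source_label: str = "") -> PeakSet:
    """Load a BED3+ file (0-based half-open) into a sorted PeakSet."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip() or ln.startswith(("#", "track", "browser")):
                continue
            cells = ln.split()
            if len(cells) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(cells[1]), int(cells[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            intervals.append((cells[0], start, end))
    return PeakSet(intervals, source_label=source_label or os.path.basename(path))


def write_grn(result, path: str) -> None:
    """Write a GRNResult as TSV: regulator, target, posterior, strength, sign.

    Rows are ordered by descending posterior then lexicographically, so
    repeated runs diff cleanly.  Edges with zero posterior are omitted.
    """
    rows = []
    for i, target in enumerate(result.gene_ids):
        for j, reg in enumerate(result.regulator_ids):
            p = result.posterior[i, j]
            if p <= 0.0:
                continue
            b = result.strength[i, j]
            sign = "activator" if b > 0 else ("inhibitor" if b < 0 else "ambiguous")
            rows.append((reg, target, p, b, sign))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    out = ["regulator\ttarget\tposterior_probability\tstrength\tsign"]
    for reg, tgt, p, b, sign in rows:
        out.append(f"{reg}\t{tgt}\t{p:.6f}\t{b:.6f}\t{sign}")
    _atomic_write(path, "\n".join(out) + "\n")


def read_grn(path: str) -> pd.DataFrame:
    """Read a written GRN table back as a DataFrame."""
    df = pd.read_csv(path, sep="\t")
    expected = ["regulator", "target", "posterior_probability", "strength", "sign"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}")
    return df


def write_gold_standard(gold: GoldStandard, path: str) -> None:
    """Write every regulator x target pair with a 0/1 label (sorted)."""
    out = []
    for reg in sorted(gold.regulator_universe):
        for tgt in sorted(gold.target_universe):
            if reg == tgt and not gold.allow_self:
                continue
            out.append(f"{reg}\t{tgt}\t{int((reg, tgt) in gold.edges)}")
    _atomic_write(path, "\n".join(out) + "\n")


def write_expression_tsv(ds: ExpressionDataset, prefix: str) -> list[str]:
    """Write one genes-in-rows TSV per series; returns the paths."""
    paths = []
    for k, (mat, ts) in enumerate(zip(ds.series, ds.time_stamps)):
        df = pd.DataFrame(mat, index=ds.gene_ids, columns=[f"{t:g}" for t in ts])
        path = f"{prefix}_series{k}.tsv"
        _atomic_write(path, df.to_csv(sep="\t", index_label="gene"))
        paths.append(path)
    return paths
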