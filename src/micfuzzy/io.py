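"""Reading, writing and preparing DREAM-style time-series expression data.

The expression format is the one used by the DREAM in-silico network
challenges: a tab-separated file whose first column is ``Time`` and whose
remaining columns are gene names.  A file may stack several independent
time series (perturbation experiments); blocks are delimited by a repeated
header line, a blank line, or — under the ``time-reset`` dialect — by a
non-increasing jump in the Time column.

Gold standards are two- or three-column edge lists
(``regulator<TAB>target[<TAB>label]``), also the DREAM convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionDataset",
    "GoldStandard",
    "LaggedPairSample",
    "ExpressionParseError",
    "NormalizationWarning",
    "read_timeseries",
    "write_timeseries",
    "minmax_normalize",
    "lagged_pairs",
    "read_goldstandard",
    "write_goldstandard",
]


class ExpressionParseError(ValueError):
    """Raised when an expression or gold-standard file is malformed."""


class NormalizationWarning(UserWarning):
    """Emitted when a constant gene is flattened to zero by normalization."""


@dataclass
class ExpressionDataset:
    """Gene-by-timepoint expression values grouped into independent series.

    Attributes
    ----------
    gene_ids:
        Ordered gene names (input file order; all deterministic iteration
        in the package follows this order).
    series:
        One ``(timepoints, genes)`` float array per independent time series.
    time_stamps:
        One array of time values per series, aligned with ``series``.
    normalized:
        True once values have been min-max scaled to [0, 1] per gene.
    """

    gene_ids: list[str]
    series: list[np.ndarray]
    time_stamps: list[np.ndarray]
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ExpressionParseError("duplicate gene names in dataset")
        for k, (mat, ts) in enumerate(zip(self.series, self.time_stamps)):
            if mat.ndim != 2 or mat.shape[1] != len(self.gene_ids):
                raise ExpressionParseError(
                    f"series {k}: expected shape (T, {len(self.gene_ids)}), got {mat.shape}"
                )
            if mat.shape[0] < 3:
                raise ExpressionParseError(
                    f"series {k} has {mat.shape[0]} timepoints; lagged prediction needs >= 3"
                )
            if len(ts) != mat.shape[0]:
                raise ExpressionParseError(f"series {k}: time stamps do not match row count")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def total_timepoints(self) -> int:
        return sum(mat.shape[0] for mat in self.series)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene name: {gene!r}") from None

    def gene_values(self, gene: str) -> list[np.ndarray]:
        """Per-series expression trajectories of one gene."""
        g = self.gene_index(gene)
        return [mat[:, g] for mat in self.series]

    def pooled_gene_values(self, gene: str) -> np.ndarray:
        g = self.gene_index(gene)
        return np.concatenate([mat[:, g] for mat in self.series])


@dataclass
class GoldStandard:
    """Known directed (regulator, target) interactions for evaluation."""

    edges: set[tuple[str, str]]
    gene_universe: list[str]
    labels: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        universe = set(self.gene_universe)
        for reg, tgt in self.edges:
            if reg == tgt:
                raise ValueError(f"self-loop ({reg}, {tgt}) in gold standard")
            if reg not in universe or tgt not in universe:
                raise ValueError(f"edge ({reg}, {tgt}) outside the gene universe")


@dataclass
class LaggedPairSample:
    """Paired samples (regulator at t, target at t+1) pooled across series.

    No pair straddles a boundary between two independent series.
    """

    regulator_values: np.ndarray
    target_values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.regulator_values)

    def __post_init__(self) -> None:
        if len(self.regulator_values) != len(self.target_values):
            raise ValueError("regulator and target sequences differ in length")


# ---------------------------------------------------------------------------
# expression file parsing


def _parse_header(fields: list[str], lineno: int) -> list[str]:
    if not fields or fields[0] != "Time":
        raise ExpressionParseError(f"line {lineno}: first column must be named 'Time'")
    genes = fields[1:]
    if not genes:
        raise ExpressionParseError(f"line {lineno}: no gene columns")
    if len(set(genes)) != len(genes):
        raise ExpressionParseError(f"line {lineno}: duplicate gene names in header")
    return genes


def read_timeseries(path: str | Path, dialect: str = "header-per-block") -> ExpressionDataset:
    """Read a DREAM-format expression file into an :class:`ExpressionDataset`.

    Parameters
    ----------
    path:
        Tab-separated file; first column ``Time``, remaining columns genes.
    dialect:
        ``"header-per-block"`` — blocks are delimited by repeated header
        lines or blank lines only.  ``"time-reset"`` — additionally start a
        new block whenever the Time column fails to increase.
    """
    if dialect not in ("header-per-block", "time-reset"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    text = Path(path).read_text(encoding="utf-8")

    genes: list[str] | None = None
    header_fields: list[str] | None = None
    blocks: list[list[list[float]]] = []
    times: list[list[float]] = []
    current_rows: list[list[float]] = []
    current_times: list[float] = []

    def close_block() -> None:
        nonlocal current_rows, current_times
        if current_rows:
            blocks.append(current_rows)
            times.append(current_times)
            current_rows, current_times = [], []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            close_block()
            continue
        fields = line.split("\t")
        if genes is None:
            genes = _parse_header(fields, lineno)
            header_fields = fields
            continue
        if fields == header_fields:  # repeated header: new block
            close_block()
            continue
        if len(fields) != len(genes) + 1:
            raise ExpressionParseError(
                f"line {lineno}: expected {len(genes) + 1} fields, got {len(fields)}"
            )
        try:
            values = [float(v) for v in fields]
        except ValueError as exc:
            raise ExpressionParseError(f"line {lineno}: non-numeric value ({exc})") from None
        t = values[0]
        if dialect == "time-reset" and current_times and t <= current_times[-1]:
            close_block()
        current_times.append(t)
        current_rows.append(values[1:])
    close_block()

    if genes is None:
        raise ExpressionParseError("empty file: no header line")
    if not blocks:
        raise ExpressionParseError("no data rows")
    series = [np.asarray(rows, dtype=float) for rows in blocks]
    stamps = [np.asarray(ts, dtype=float) for ts in times]
    return ExpressionDataset(gene_ids=list(genes), series=series, time_stamps=stamps)


def write_timeseries(ds: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset back to DREAM format (header repeated per block).

    Values are printed with 17 significant digits, so a write/read round
    trip reproduces them exactly and preserves series boundaries.
    """
    header = "Time\t" + "\t".join(ds.gene_ids)
    lines: list[str] = []
    for k, (mat, ts) in enumerate(zip(ds.series, ds.time_stamps)):
        lines.append(header)
        for t, row in zip(ts, mat):
            lines.append("\t".join(f"{v:.17g}" for v in (t, *row)))
        if k != ds.n_series - 1:
            lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# normalization and lagged sampling


def minmax_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Min-max scale every gene to [0, 1], pooling all series per gene.

    Already-normalized datasets are returned unchanged (idempotent).
    Constant genes are mapped to all zeros and a
    :class:`NormalizationWarning` is emitted instead of raising, so
    degenerate simulated inputs keep the pipeline running.
    """
    if ds.normalized:
        return ds
    pooled = np.concatenate(ds.series, axis=0)
    lo = pooled.min(axis=0)
    hi = pooled.max(axis=0)
    span = hi - lo
    constant = span == 0
    for g in np.flatnonzero(constant):
        warnings.warn(
            f"gene {ds.gene_ids[g]!r} is constant; normalized to all zeros",
            NormalizationWarning,
            stacklevel=2,
        )
    safe_span = np.where(constant, 1.0, span)
    new_series = []
    for mat in ds.series:
        scaled = (mat - lo) / safe_span
        scaled[:, constant] = 0.0
        new_series.append(scaled)
    return replace(ds, series=new_series, normalized=True)


def lagged_pairs(ds: ExpressionDataset, regulator: str, target: str) -> LaggedPairSample:
    """Collect (regulator at t, target at t+1) pairs within each series.

    Pairs never cross a series boundary; n = sum over series of (T_s - 1).
    """
    r = ds.gene_index(regulator)
    g = ds.gene_index(target)
    xs = [mat[:-1, r] for mat in ds.series]
    ys = [mat[1:, g] for mat in ds.series]
    return LaggedPairSample(np.concatenate(xs), np.concatenate(ys))


# ---------------------------------------------------------------------------
# gold standards


def read_goldstandard(path: str | Path, gene_universe: Sequence[str]) -> GoldStandard:
    """Read a DREAM gold-standard edge list.

    Three columns ``regulator, target, label`` with label in {0, 1}, or two
    columns with implicit label 1.  Self-loops are dropped with a warning
    (the model does not consider self-regulation).
    """
    universe = set(gene_universe)
    edges: set[tuple[str, str]] = set()
    labels: dict[tuple[str, str], int] = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) == 2:
            reg, tgt = fields
            label = 1
        elif len(fields) == 3:
            reg, tgt, label_str = fields
            if label_str not in ("0", "1"):
                raise ExpressionParseError(
                    f"line {lineno}: label must be 0 or 1, got {label_str!r}"
                )
            label = int(label_str)
        else:
            raise ExpressionParseError(f"line {lineno}: expected 2 or 3 columns")
        if reg not in universe:
            raise ExpressionParseError(f"line {lineno}: gene {reg!r} outside the universe")
        if tgt not in universe:
            raise ExpressionParseError(f"line {lineno}: gene {tgt!r} outside the universe")
        if reg == tgt:
            warnings.warn(
                f"line {lineno}: self-loop ({reg}, {tgt}) dropped", UserWarning, stacklevel=2
            )
            continue
        labels[(reg, tgt)] = label
        if label == 1:
            edges.add((reg, tgt))
    return GoldStandard(edges=edges, gene_universe=list(gene_universe), labels=labels)


def write_goldstandard(gold: GoldStandard, path: str | Path) -> None:
    lines = [f"{reg}\t{tgt}\t1" for reg, tgt in sorted(gold.edges)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
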