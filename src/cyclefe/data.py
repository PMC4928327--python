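"""Expression-matrix containers and readers.

A time-course experiment is held as a gene × time-point matrix. Two text
dialects are supported: the GEO series-matrix format (metadata lines prefixed
``!``, the numeric table fenced by ``!series_matrix_table_begin`` /
``!series_matrix_table_end``) and a plain tab-separated table whose first row
carries time labels and whose first column carries gene identifiers.

Per-sample normalization centres every column to mean 0 and scales it so that
(1/N) Σ_i x_ij² = 1 (population convention, divisor N). No per-gene
normalization is applied here.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "na", "nan", "null", "none"}


class FormatError(ValueError):
    """The file does not follow the expected dialect."""


class ParseError(ValueError):
    """A cell or row could not be interpreted."""


@dataclass
class ExpressionMatrix:
    """Gene × time-point expression values.

    Attributes
    ----------
    gene_ids : list of str
        Row identifiers (probes or gene symbols), length N.
    time_labels : list of str
        Column labels, length M. Downstream math treats columns as the
        ordered integer grid j = 1..M; real clock times are labels only.
    values : ndarray of shape (N, M)
    normalized : bool
        True once per-sample normalization has been applied.
    n_dropped : int
        Number of gene rows dropped at load time because of missing cells.
    """

    gene_ids: list[str]
    time_labels: list[str]
    values: np.ndarray
    normalized: bool = False
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} rows")
        if len(self.time_labels) != m:
            raise ValueError(f"{len(self.time_labels)} time labels for {m} columns")
        if n < 2 or m < 3:
            raise ValueError(f"need at least 2 genes and 3 time points, got {n}×{m}")
        if np.isnan(self.values).any():
            raise ValueError("missing values must be resolved before construction")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneList:
    """An ordered list of gene identifiers with a provenance label."""

    gene_ids: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dups = [g for g in self.gene_ids if g in seen or seen.add(g)]
        if dups:
            raise ValueError(f"duplicate gene ids: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == token[-1] == '"':
        token = token[1:-1]
    return token


def _build_matrix(
    gene_ids: list[str],
    time_labels: list[str],
    rows: list[list[str]],
) -> ExpressionMatrix:
    """Convert text cells to floats, dropping genes with missing entries."""
    kept_ids: list[str] = []
    kept_rows: list[list[float]] = []
    n_dropped = 0
    for gid, row in zip(gene_ids, rows):
        parsed: list[float] = []
        missing = False
        for col, cell in enumerate(row):
            cell = _unquote(cell)
            if cell.lower() in _MISSING_TOKENS:
                missing = True
                break
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"non-numeric cell {cell!r} in row {gid!r}, "
                    f"column {time_labels[col]!r}"
                ) from None
        if missing:
            n_dropped += 1
            continue
        kept_ids.append(gid)
        kept_rows.append(parsed)
    if n_dropped:
        logger.info("dropped %d gene(s) with missing values", n_dropped)
    return ExpressionMatrix(
        gene_ids=kept_ids,
        time_labels=time_labels,
        values=np.array(kept_rows, dtype=float),
        n_dropped=n_dropped,
    )


def read_series_matrix(path) -> ExpressionMatrix:
    """Read a GEO series-matrix text file.

    Metadata lines (prefixed ``!``) are ignored, except ``!Sample_title``
    whose fields become the time labels. The table between the begin/end
    markers supplies gene ids (first column) and values. Genes with any
    missing cell are dropped and counted.
    """
    sample_titles: list[str] | None = None
    table_rows: list[list[str]] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path, newline="") as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if line.startswith("!"):
                if line.startswith("!Sample_title"):
                    sample_titles = [_unquote(t) for t in line.split("\t")[1:]]
                continue
            if in_table and line:
                table_rows.append(line.split("\t"))
    if not (saw_begin and saw_end):
        raise FormatError(f"{path}: series-matrix table markers not found")
    if len(table_rows) < 2:
        raise FormatError(f"{path}: empty series-matrix table")
    header = [_unquote(t) for t in table_rows[0][1:]]
    labels = sample_titles if sample_titles and len(sample_titles) == len(header) else header
    gene_ids = [_unquote(r[0]) for r in table_rows[1:]]
    rows = [r[1:] for r in table_rows[1:]]
    for gid, row in zip(gene_ids, rows):
        if len(row) != len(labels):
            raise ParseError(f"row {gid!r} has {len(row)} cells, expected {len(labels)}")
    return _build_matrix(gene_ids, labels, rows)


def read_tsv_matrix(path) -> ExpressionMatrix:
    """Read a plain tab-separated gene × time-point table.

    First row = time labels, first column = gene ids. Both Unix and Windows
    line endings are accepted. Ragged rows and duplicate gene ids are errors.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        records = [row for row in reader if row and any(c.strip() for c in row)]
    if len(records) < 2:
        raise FormatError(f"{path}: no data rows")
    labels = [_unquote(t) for t in records[0][1:]]
    gene_ids = [_unquote(r[0]) for r in records[1:]]
    for gid, row in zip(gene_ids, records[1:]):
        if len(row) - 1 != len(labels):
            raise ParseError(
                f"ragged row {gid!r}: {len(row) - 1} cells, expected {len(labels)}"
            )
    seen: set[str] = set()
    dups = sorted({g for g in gene_ids if g in seen or seen.add(g)})
    if dups:
        raise ParseError(f"duplicate gene ids: {dups}")
    return _build_matrix(gene_ids, labels, [r[1:] for r in records[1:]])


def write_tsv_matrix(X: ExpressionMatrix, path) -> None:
    """Write the matrix in the plain TSV dialect read by :func:`read_tsv_matrix`."""
    with open(path, "w", newline="") as fh:
        fh.write("gene_id\t" + "\t".join(X.time_labels) + "\n")
        for gid, row in zip(X.gene_ids, X.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_gene_list(path, provenance: str = "") -> GeneList:
    """Read a one-identifier-per-line gene list."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return GeneList(gene_ids=ids, provenance=provenance or str(path))


def write_gene_list(genes: GeneList | Sequence[str], path) -> None:
    ids = genes.gene_ids if isinstance(genes, GeneList) else list(genes)
    with open(path, "w") as fh:
        for g in ids:
            fh.write(g + "\n")


def normalize_samples(X: ExpressionMatrix) -> ExpressionMatrix:
    """Centre and scale each sample (column) to mean 0 and (1/N) Σ x² = 1.

    The divisor is the gene count N (population convention). No row scaling
    is performed. Raises if a column has zero variance.
    """
    values = X.values
    means = values.mean(axis=0)
    centred = values - means
    scale = np.sqrt((centred**2).mean(axis=0))
    bad = np.flatnonzero(scale == 0)
    if bad.size:
        names = [X.time_labels[j] for j in bad]
        raise ValueError(f"zero variance in column(s): {names}")
    return replace(X, values=centred / scale, normalized=True)


def mask_time_points(
    X: ExpressionMatrix, keep: Callable[[int], bool]
) -> ExpressionMatrix:
    """Filter time points by a predicate on the 1-based time index j.

    Column order is preserved. If the input was normalized, normalization is
    re-applied to the surviving columns so the column statistics still hold.
    """
    idx = [j for j in range(X.n_times) if keep(j + 1)]
    if len(idx) < 3:
        raise ValueError(f"only {len(idx)} time points survive the mask; need ≥ 3")
    out = ExpressionMatrix(
        gene_ids=list(X.gene_ids),
        time_labels=[X.time_labels[j] for j in idx],
        values=X.values[:, idx],
        normalized=False,
        n_dropped=X.n_dropped,
    )
    if X.normalized:
        out = normalize_samples(out)
    return out
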