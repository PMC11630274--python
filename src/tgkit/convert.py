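"""Build transmission graphs from pairwise matrices and tables.

Transmission-inference tools commonly emit a square labelled matrix of
pairwise relatedness: SNP distances (small = related), directed transmission
probabilities (large = related, generally asymmetric), or IBD fractions in
[0, 1]. Conversion applies a threshold under one of two conventions —
``at_most`` for distances, ``at_least`` for similarities/probabilities — and
emits one edge per qualifying pair carrying the matrix value as a float
attribute. Every label becomes a node whether or not it gains an edge, so
cluster-size statistics are not silently truncated.

Long-format edge tables and node/edge metadata tables round out the inputs.
Delimiters are auto-detected from the file extension (.csv → comma,
.tsv/.txt → tab) with an explicit override.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    ConversionError,
    DuplicateEdgeError,
    MergeError,
    SelfLoopError,
    TableFormatError,
)
from .model import AttrValue, Edge, Node, TransmissionGraph

#: Cell contents treated as "no value, no edge possible".
MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan", "na"})

#: Maximum relative asymmetry tolerated when converting in undirected mode.
SYMMETRY_RTOL = 1e-9


@dataclass
class PairwiseTable:
    """A labelled square matrix of relatedness values awaiting conversion.

    ``labels`` order follows the input file; ``values`` is float with NaN
    marking missing cells (a missing cell never yields an edge).
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise TableFormatError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise TableFormatError("duplicate sample labels in pairwise table")

    @property
    def n(self) -> int:
        return len(self.labels)

    def is_symmetric(self, rtol: float = SYMMETRY_RTOL) -> bool:
        a, at = self.values, self.values.T
        both_nan = np.isnan(a) & np.isnan(at)
        close = np.isclose(a, at, rtol=rtol, atol=0.0, equal_nan=False)
        off = ~np.eye(self.n, dtype=bool)
        return bool(np.all((close | both_nan)[off]))


@dataclass
class ConversionSpec:
    """How to turn matrix cells into edges.

    ``comparison='at_most'`` is the distance convention (value ≤ threshold
    links a pair, e.g. ≤50 SNPs); ``'at_least'`` is the similarity and
    probability convention (value ≥ threshold, e.g. IBD fraction ≥ 0.2).
    Both thresholds are inclusive.
    """

    attribute_name: str
    threshold: float
    comparison: str = "at_most"  # "at_most" | "at_least"
    directedness: str = "undirected"  # "undirected" | "directed"

    def __post_init__(self) -> None:
        if self.comparison not in ("at_most", "at_least"):
            raise ConversionError(f"unknown comparison {self.comparison!r}")
        if self.directedness not in ("undirected", "directed"):
            raise ConversionError(f"unknown directedness {self.directedness!r}")

    def passes(self, value: float) -> bool:
        if math.isnan(value):
            return False
        if self.comparison == "at_most":
            return value <= self.threshold
        return value >= self.threshold


def _delimiter_for(path: Union[str, os.PathLike], delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def read_pairwise_table(path: Union[str, os.PathLike], delimiter: str | None = None) -> PairwiseTable:
    """Read a labelled square matrix from delimited text.

    The first row holds column labels, the first column row labels; both
    sequences must be identical. Cells are numeric or a missing token
    (empty, ``NA``, ``NaN``). Errors name the offending row/column.
    """
    sep = _delimiter_for(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise TableFormatError(f"cannot parse {path}: {exc}") from exc
    row_labels = [str(x) for x in df.index]
    col_labels = [str(x) for x in df.columns]
    if len(row_labels) != len(col_labels):
        raise TableFormatError(
            f"matrix is not square: {len(row_labels)} rows vs {len(col_labels)} columns"
        )
    if row_labels != col_labels:
        raise TableFormatError(
            "row labels do not match column labels "
            f"(first difference at position "
            f"{next(i for i, (r, c) in enumerate(zip(row_labels, col_labels)) if r != c)})"
        )
    n = len(row_labels)
    values = np.full((n, n), np.nan)
    for i, row in enumerate(df.itertuples(index=False)):
        for j, cell in enumerate(row):
            cell = str(cell).strip()
            if cell in MISSING_TOKENS:
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise TableFormatError(
                    f"non-numeric cell {cell!r} at row {row_labels[i]!r}, "
                    f"column {col_labels[j]!r}"
                ) from exc
    return PairwiseTable(labels=row_labels, values=values)


def from_pairwise_table(table: PairwiseTable, spec: ConversionSpec) -> TransmissionGraph:
    """Convert a pairwise matrix into a thresholded transmission graph.

    All labels become nodes. Undirected mode requires a (tolerantly)
    symmetric matrix and emits one edge per unordered pair whose value
    satisfies the comparison; directed mode reads every ordered off-diagonal
    cell independently, so a pair may get one edge per direction. The
    diagonal is always ignored, and a probability of exactly zero never
    satisfies a positive ``at_least`` threshold — zero-imputed
    between-cluster cells therefore produce no edges.
    """
    directed = spec.directedness == "directed"
    if not directed and not table.is_symmetric():
        raise ConversionError(
            "matrix is asymmetric beyond tolerance; "
            "use directed mode for per-direction values"
        )
    nodes = [Node(str(label)) for label in table.labels]
    edges: list[Edge] = []
    n = table.n
    v = table.values
    if directed:
        for i in range(n):
            for j in range(n):
                if i != j and spec.passes(v[i, j]):
                    edges.append(
                        Edge(str(table.labels[i]), str(table.labels[j]),
                             {spec.attribute_name: float(v[i, j])})
                    )
    else:
        for i in range(n):
            for j in range(i + 1, n):
                if spec.passes(v[i, j]):
                    edges.append(
                        Edge(str(table.labels[i]), str(table.labels[j]),
                             {spec.attribute_name: float(v[i, j])})
                    )
    return TransmissionGraph(directed=directed, nodes=nodes, edges=edges)


def _coerce_cell(value: object) -> AttrValue:
    """Turn a table cell into a trjson attribute value, preserving kind."""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, (np.integer, int)):
        return int(value)
    if isinstance(value, (np.floating, float)):
        return float(value)
    return str(value)


def from_edge_table(
    rows: Union[pd.DataFrame, Iterable[Mapping[str, object]]],
    directed: bool = False,
    source_column: str = "source",
    target_column: str = "target",
) -> TransmissionGraph:
    """Build a graph from long-format edge rows (sparse alternative to a matrix).

    Nodes are the union of mentioned samples in first-appearance order;
    every non-endpoint column becomes an edge attribute. Duplicate pairs
    (under the requested directedness) and self-loops are errors.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    for col in (source_column, target_column):
        if col not in rows.columns:
            raise TableFormatError(f"edge table lacks required column {col!r}")
    attr_cols = [c for c in rows.columns if c not in (source_column, target_column)]
    node_order: list[str] = []
    seen_nodes: set[str] = set()
    seen_pairs: set[object] = set()
    edges: list[Edge] = []
    for idx, row in rows.iterrows():
        src = str(row[source_column])
        tgt = str(row[target_column])
        if src == tgt:
            raise SelfLoopError(f"row {idx}: source equals target ({src!r})")
        pair = (src, tgt) if directed else frozenset((src, tgt))
        if pair in seen_pairs:
            raise DuplicateEdgeError(
                f"row {idx}: duplicate edge for pair ({src!r}, {tgt!r}) "
                f"under {'directed' if directed else 'undirected'} semantics"
            )
        seen_pairs.add(pair)
        for sample in (src, tgt):
            if sample not in seen_nodes:
                seen_nodes.add(sample)
                node_order.append(sample)
        attributes = {
            c: _coerce_cell(row[c])
            for c in attr_cols
            if not (isinstance(row[c], float) and math.isnan(row[c]))
        }
        edges.append(Edge(src, tgt, attributes))
    return TransmissionGraph(
        directed=directed,
        nodes=[Node(nid) for nid in node_order],
        edges=edges,
    )


@dataclass
class MergeOutcome:
    """Result of a metadata merge: the new graph plus unmatched-row report."""

    graph: TransmissionGraph
    unmatched: list[str] = field(default_factory=list)
    matched: int = 0


def read_metadata_table(path: Union[str, os.PathLike], delimiter: str | None = None) -> pd.DataFrame:
    """Read a metadata table from delimited text (delimiter by extension)."""
    sep = _delimiter_for(path, delimiter)
    return pd.read_csv(path, sep=sep)


def merge_node_metadata(
    graph: TransmissionGraph,
    table: pd.DataFrame,
    id_column: str = "id",
    overwrite: bool = False,
) -> MergeOutcome:
    """Annotate nodes with table rows matched on ``id_column``.

    Topology is untouched. Rows whose id matches no node are reported in
    ``unmatched``, not fatal — clinical tables routinely cover more samples
    than the graph at hand. A collision with an existing node attribute is
    an error unless ``overwrite`` is set.
    """
    if id_column not in table.columns:
        raise MergeError(f"metadata table lacks id column {id_column!r}")
    ids = table[id_column].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise MergeError(f"duplicated id {dup!r} in metadata table")
    out = graph.copy()
    by_id = {n.id: n for n in out.nodes}
    attr_cols = [c for c in table.columns if c != id_column]
    unmatched: list[str] = []
    matched = 0
    for _, row in table.iterrows():
        nid = str(row[id_column])
        node = by_id.get(nid)
        if node is None:
            unmatched.append(nid)
            continue
        matched += 1
        for col in attr_cols:
            value = row[col]
            if isinstance(value, float) and math.isnan(value):
                continue
            if col in node.attributes and not overwrite:
                raise MergeError(
                    f"node {nid!r} already has attribute {col!r}; pass overwrite to replace"
                )
            node.attributes[col] = _coerce_cell(value)
    return MergeOutcome(graph=out, unmatched=unmatched, matched=matched)


def merge_edge_metadata(
    graph: TransmissionGraph,
    table: pd.DataFrame,
    source_column: str = "source",
    target_column: str = "target",
    overwrite: bool = False,
) -> MergeOutcome:
    """Annotate edges with table rows matched on their endpoints.

    Matching respects the graph's directedness: undirected graphs match the
    unordered pair, directed graphs the ordered one. Rows addressing no
    existing edge are reported, not fatal.
    """
    for col in (source_column, target_column):
        if col not in table.columns:
            raise MergeError(f"metadata table lacks endpoint column {col!r}")
    out = graph.copy()
    by_pair = {e.pair(out.directed): e for e in out.edges}
    attr_cols = [c for c in table.columns if c not in (source_column, target_column)]
    unmatched: list[str] = []
    matched = 0
    seen: set[object] = set()
    for idx, row in table.iterrows():
        src, tgt = str(row[source_column]), str(row[target_column])
        pair = (src, tgt) if out.directed else frozenset((src, tgt))
        if pair in seen:
            raise MergeError(f"row {idx}: duplicate metadata for edge ({src!r}, {tgt!r})")
        seen.add(pair)
        edge = by_pair.get(pair)
        if edge is None:
            unmatched.append(f"{src}->{tgt}" if out.directed else f"{src}--{tgt}")
            continue
        matched += 1
        for col in attr_cols:
            value = row[col]
            if isinstance(value, float) and math.isnan(value):
                continue
            if col in edge.attributes and not overwrite:
                raise MergeError(
                    f"edge ({src!r}, {tgt!r}) already has attribute {col!r}; "
                    "pass overwrite to replace"
                )
            edge.attributes[col] = _coerce_cell(value)
    return MergeOutcome(graph=out, unmatched=unmatched, matched=matched)


def write_pairwise_table(table: PairwiseTable, path: Union[str, os.PathLike],
                         delimiter: str | None = None) -> None:
    """Write a pairwise table back to delimited text (NaN as empty cells)."""
    sep = _delimiter_for(path, delimiter)
    df = pd.DataFrame(table.values, index=table.labels, columns=table.labels)
    df.to_csv(path, sep=sep, na_rep="")
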