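"""Matrix/table → graph conversion and metadata merging."""

import numpy as np
import pandas as pd
import pytest

from tgkit.convert import (
    ConversionSpec,
    PairwiseTable,
    from_edge_table,
    from_pairwise_table,
    merge_edge_metadata,
    merge_node_metadata,
    read_pairwise_table,
)
from tgkit.errors import (
    ConversionError,
    DuplicateEdgeError,
    MergeError,
    SelfLoopError,
    TableFormatError,
)


def brute_force_edges(table: PairwiseTable, spec: ConversionSpec) -> set:
    """Independent double loop over all pairs (the conversion oracle)."""
    passes = (
        (lambda v: v <= spec.threshold)
        if spec.comparison == "at_most"
        else (lambda v: v >= spec.threshold)
    )
    out = set()
    n = table.n
    for i in range(n):
        for j in range(n):
            if i == j or np.isnan(table.values[i, j]):
                continue
            if not passes(table.values[i, j]):
                continue
            if spec.directedness == "directed":
                out.add((table.labels[i], table.labels[j]))
            else:
                out.add(frozenset((table.labels[i], table.labels[j])))
    return out


def edge_set(graph) -> set:
    return {e.pair(graph.directed) for e in graph.edges}


def random_symmetric(rng, n, scale=100.0):
    values = rng.uniform(0, scale, (n, n))
    values = (values + values.T) / 2
    np.fill_diagonal(values, 0.0)
    return PairwiseTable([f"S{i}" for i in range(n)], values)


class TestReadPairwiseTable:
    def test_reads_labels_in_file_order(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(",A,B,C\nA,0,1,2\nB,1,0,3\nC,2,3,0\n")
        table = read_pairwise_table(path)
        assert table.labels == ["A", "B", "C"]
        assert table.values[0, 2] == 2.0

    def test_label_order_mismatch_is_an_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(",A,B\nB,0,1\nA,1,0\n")
        with pytest.raises(TableFormatError, match="label"):
            read_pairwise_table(path)

    def test_ragged_matrix_is_a_shape_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(",A,B,C\nA,0,1,2\nB,1,0,3\n")
        with pytest.raises(TableFormatError):
            read_pairwise_table(path)

    def test_missing_tokens_become_missing_not_zero(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(",A,B\nA,0,NA\nB,,0\n")
        table = read_pairwise_table(path)
        assert np.isnan(table.values[0, 1]) and np.isnan(table.values[1, 0])

    def test_non_numeric_cell_names_location(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(",A,B\nA,0,oops\nB,1,0\n")
        with pytest.raises(TableFormatError, match="oops"):
            read_pairwise_table(path)

    def test_tab_delimiter_from_extension(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("\tA\tB\nA\t0\t5\nB\t5\t0\n")
        table = read_pairwise_table(path)
        assert table.values[0, 1] == 5.0


class TestFromPairwiseTable:
    def test_single_clonal_pair_at_ibd_threshold(self):
        n = 5
        values = np.full((n, n), 0.01)
        np.fill_diagonal(values, 1.0)
        values[1, 3] = values[3, 1] = 0.95
        table = PairwiseTable([f"S{i}" for i in range(n)], values)
        g = from_pairwise_table(
            table, ConversionSpec("ibd_fraction", 0.2, "at_least", "undirected")
        )
        assert len(g.edges) == 1
        assert edge_set(g) == {frozenset(("S1", "S3"))}
        assert g.edges[0].attributes["ibd_fraction"] == 0.95

    def test_no_cell_satisfying_threshold_keeps_all_nodes(self):
        rng = np.random.default_rng(0)
        table = random_symmetric(rng, 8, scale=100.0)
        g = from_pairwise_table(table, ConversionSpec("d", -1.0, "at_most"))
        assert len(g.nodes) == 8 and len(g.edges) == 0

    @pytest.mark.parametrize("comparison", ["at_most", "at_least"])
    @pytest.mark.parametrize("directedness", ["undirected", "directed"])
    def test_oracle_equivalence_random_tables(self, comparison, directedness):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(5, 31))
            if directedness == "directed":
                values = rng.uniform(0, 100, (n, n))
                np.fill_diagonal(values, 0.0)
                table = PairwiseTable([f"S{i}" for i in range(n)], values)
            else:
                table = random_symmetric(rng, n)
            spec = ConversionSpec("v", float(rng.uniform(0, 100)), comparison, directedness)
            g = from_pairwise_table(table, spec)
            assert edge_set(g) == brute_force_edges(table, spec)
            assert g.node_ids() == table.labels

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        table = random_symmetric(rng, 15)
        t1, t2 = 30.0, 60.0
        e1 = edge_set(from_pairwise_table(table, ConversionSpec("d", t1, "at_most")))
        e2 = edge_set(from_pairwise_table(table, ConversionSpec("d", t2, "at_most")))
        assert e1 <= e2
        s1 = edge_set(from_pairwise_table(table, ConversionSpec("d", t2, "at_least")))
        s2 = edge_set(from_pairwise_table(table, ConversionSpec("d", t1, "at_least")))
        assert s1 <= s2

    def test_directed_on_symmetric_matrix_doubles_undirected_edges(self):
        rng = np.random.default_rng(5)
        table = random_symmetric(rng, 12)
        spec_u = ConversionSpec("d", 50, "at_most", "undirected")
        spec_d = ConversionSpec("d", 50, "at_most", "directed")
        undirected = edge_set(from_pairwise_table(table, spec_u))
        directed = edge_set(from_pairwise_table(table, spec_d))
        assert len(directed) == 2 * len(undirected)
        assert {frozenset(p) for p in directed} == undirected

    def test_asymmetric_matrix_rejected_in_undirected_mode(self):
        values = np.array([[0.0, 1.0], [2.0, 0.0]])
        table = PairwiseTable(["A", "B"], values)
        with pytest.raises(ConversionError, match="directed"):
            from_pairwise_table(table, ConversionSpec("d", 10, "at_most"))

    def test_missing_cells_never_yield_edges(self):
        values = np.array([[0.0, np.nan], [np.nan, 0.0]])
        table = PairwiseTable(["A", "B"], values)
        g = from_pairwise_table(table, ConversionSpec("d", 1e9, "at_most"))
        assert g.edges == []

    def test_zero_probability_yields_no_edge_at_positive_threshold(self):
        values = np.array([[0.0, 0.0], [0.4, 0.0]])
        table = PairwiseTable(["A", "B"], values)
        g = from_pairwise_table(table, ConversionSpec("probability", 0.01, "at_least", "directed"))
        assert edge_set(g) == {("B", "A")}

    def test_edge_attribute_is_float_even_when_integral(self):
        values = np.array([[0.0, 3.0], [3.0, 0.0]])
        g = from_pairwise_table(
            PairwiseTable(["A", "B"], values), ConversionSpec("d", 10, "at_most")
        )
        assert isinstance(g.edges[0].attributes["d"], float)


class TestFromEdgeTable:
    def test_undirected_rows(self):
        rows = pd.DataFrame(
            [{"source": "A", "target": "B", "dist": 3},
             {"source": "B", "target": "C", "dist": 7}]
        )
        g = from_edge_table(rows, directed=False)
        assert g.node_ids() == ["A", "B", "C"]
        assert len(g.edges) == 2
        assert g.edges[0].attributes == {"dist": 3}

    def test_duplicate_unordered_pair_is_an_error(self):
        rows = pd.DataFrame(
            [{"source": "A", "target": "B"}, {"source": "B", "target": "A"}]
        )
        with pytest.raises(DuplicateEdgeError):
            from_edge_table(rows, directed=False)

    def test_directed_pair_per_direction(self):
        rows = pd.DataFrame(
            [{"source": "A", "target": "B", "p": 0.8},
             {"source": "B", "target": "A", "p": 0.1}]
        )
        g = from_edge_table(rows, directed=True)
        assert len(g.edges) == 2
        assert {(e.source, e.target) for e in g.edges} == {("A", "B"), ("B", "A")}

    def test_self_loop_row_is_an_error(self):
        rows = pd.DataFrame([{"source": "A", "target": "A"}])
        with pytest.raises(SelfLoopError):
            from_edge_table(rows)


class TestMergeNodeMetadata:
    def test_annotates_matched_nodes_only(self, simple_graph):
        table = pd.DataFrame(
            [{"id": "A", "resistance": "MDR-TB"}, {"id": "B", "resistance": "HR-TB"}]
        )
        outcome = merge_node_metadata(simple_graph, table)
        g = outcome.graph
        assert g.node("A").attributes["resistance"] == "MDR-TB"
        assert g.node("B").attributes["resistance"] == "HR-TB"
        assert "resistance" not in g.node("C").attributes
        assert outcome.matched == 2 and outcome.unmatched == []

    def test_topology_unchanged(self, simple_graph):
        table = pd.DataFrame([{"id": "A", "x": 1}])
        g = merge_node_metadata(simple_graph, table).graph
        assert g.node_ids() == simple_graph.node_ids()
        assert [(e.source, e.target) for e in g.edges] == [
            (e.source, e.target) for e in simple_graph.edges
        ]

    def test_empty_table_leaves_graph_unchanged(self, simple_graph):
        table = pd.DataFrame(columns=["id", "x"])
        outcome = merge_node_metadata(simple_graph, table)
        assert outcome.graph == simple_graph

    def test_unmatched_row_reported_not_fatal(self, simple_graph):
        table = pd.DataFrame([{"id": "Z", "x": 1}])
        outcome = merge_node_metadata(simple_graph, table)
        assert outcome.graph == simple_graph
        assert outcome.unmatched == ["Z"]

    def test_missing_id_column_is_an_error(self, simple_graph):
        with pytest.raises(MergeError, match="id"):
            merge_node_metadata(simple_graph, pd.DataFrame([{"x": 1}]))

    def test_duplicate_id_in_table_is_an_error(self, simple_graph):
        table = pd.DataFrame([{"id": "A", "x": 1}, {"id": "A", "x": 2}])
        with pytest.raises(MergeError, match="A"):
            merge_node_metadata(simple_graph, table)

    def test_collision_requires_overwrite(self, simple_graph):
        table = pd.DataFrame([{"id": "A", "region": "Elsewhere"}])
        with pytest.raises(MergeError, match="region"):
            merge_node_metadata(simple_graph, table)
        g = merge_node_metadata(simple_graph, table, overwrite=True).graph
        assert g.node("A").attributes["region"] == "Elsewhere"

    def test_input_graph_not_mutated(self, simple_graph):
        table = pd.DataFrame([{"id": "A", "x": 1}])
        merge_node_metadata(simple_graph, table)
        assert "x" not in simple_graph.node("A").attributes


class TestMergeEdgeMetadata:
    def test_unordered_match_on_undirected_graph(self, simple_graph):
        table = pd.DataFrame([{"source": "B", "target": "A", "label": "cluster1"}])
        outcome = merge_edge_metadata(simple_graph, table)
        edge = outcome.graph.edges[0]
        assert (edge.source, edge.target) == ("A", "B")
        assert edge.attributes["label"] == "cluster1"

    def test_row_for_absent_edge_reported(self, simple_graph):
        table = pd.DataFrame([{"source": "A", "target": "C", "label": "x"}])
        outcome = merge_edge_metadata(simple_graph, table)
        assert outcome.graph == simple_graph
        assert outcome.unmatched == ["A--C"]

    def test_ordered_match_on_directed_graph(self, directed_pair):
        table = pd.DataFrame([{"source": "A", "target": "B", "x": 1}])
        g = merge_edge_metadata(directed_pair, table).graph
        forward = next(e for e in g.edges if (e.source, e.target) == ("A", "B"))
        backward = next(e for e in g.edges if (e.source, e.target) == ("B", "A"))
        assert forward.attributes["x"] == 1
        assert "x" not in backward.attributes
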