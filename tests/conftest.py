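import numpy as np
import pytest

from tgkit.model import Edge, Node, TransmissionGraph


def make_random_graph(rng: np.random.Generator, directed: bool | None = None) -> TransmissionGraph:
    """A random valid transmission graph with mixed-kind attributes."""
    if directed is None:
        directed = bool(rng.integers(0, 2))
    n = int(rng.integers(2, 15))
    ids = [f"N{i}" for i in range(n)]
    nodes = []
    regions = ["Tierralta", "Other", "Cordoba"]
    for nid in ids:
        attrs = {}
        if rng.random() < 0.7:
            attrs["region"] = regions[int(rng.integers(0, 3))]
        if rng.random() < 0.5:
            attrs["age"] = int(rng.integers(1, 90))
        if rng.random() < 0.3:
            attrs["weight"] = float(np.round(rng.uniform(40, 100), 3))
        nodes.append(Node(nid, attrs))
    edges = []
    seen = set()
    n_edges = int(rng.integers(0, n * 2))
    for _ in range(n_edges):
        i, j = rng.integers(0, n, 2)
        if i == j:
            continue
        src, tgt = ids[int(i)], ids[int(j)]
        pair = (src, tgt) if directed else frozenset((src, tgt))
        if pair in seen:
            continue
        seen.add(pair)
        attrs = {"snp_distance": float(np.round(rng.uniform(0, 100), 4))}
        if rng.random() < 0.4:
            attrs["probability"] = float(np.round(rng.random(), 4))
        edges.append(Edge(src, tgt, attrs))
    return TransmissionGraph(directed=directed, nodes=nodes, edges=edges)


@pytest.fixture
def simple_graph() -> TransmissionGraph:
    """Three nodes, two undirected edges, mixed attributes."""
    return TransmissionGraph(
        directed=False,
        nodes=[
            Node("A", {"region": "Tierralta", "age": 41}),
            Node("B", {"region": "Other", "age": 33}),
            Node("C", {"region": "Tierralta"}),
        ],
        edges=[
            Edge("A", "B", {"snp_distance": 3.0}),
            Edge("B", "C", {"snp_distance": 40.0}),
        ],
    )


@pytest.fixture
def directed_pair() -> TransmissionGraph:
    """Two nodes linked in both directions with different probabilities."""
    return TransmissionGraph(
        directed=True,
        nodes=[Node("A"), Node("B")],
        edges=[
            Edge("A", "B", {"probability": 0.8}),
            Edge("B", "A", {"probability": 0.1}),
        ],
    )
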