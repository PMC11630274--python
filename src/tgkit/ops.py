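"""Graph refinement and interrogation.

The thresholded relatedness graph's connected components ARE the
single-linkage transmission clusters: two isolates fall in the same cluster
exactly when a chain of pairwise links under the cutoff connects them.
Edge direction is ignored for connectivity (weak components), matching how
distance-based clusters seed per-cluster directed inference.

Every operation here is pure — it returns a new graph and leaves its input
untouched — which is what makes composition laws (filtering at t2 then t1
equals filtering at t1 directly) literally testable. Filtering never drops
isolated nodes implicitly; `drop_isolated_nodes` is the explicit verb,
because silent node loss corrupts cluster-size statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

from .errors import UnknownNodeError
from .model import TransmissionGraph
from .query import FilterExpression, evaluate


def to_networkx(graph: TransmissionGraph) -> "nx.Graph | nx.DiGraph":
    """View a transmission graph as a networkx (Di)Graph with attributes."""
    g = nx.DiGraph() if graph.directed else nx.Graph()
    for node in graph.nodes:
        g.add_node(node.id, **node.attributes)
    for edge in graph.edges:
        g.add_edge(edge.source, edge.target, **edge.attributes)
    return g


def filter_edges(
    graph: TransmissionGraph, expr: FilterExpression, strict: bool = False
) -> TransmissionGraph:
    """Keep exactly the edges where ``expr`` is true; all nodes are retained.

    Isolated nodes produced by the refinement stay in the graph (see module
    docstring). In strict mode a missing attribute aborts with the offending
    edge identified.
    """
    out = graph.copy()
    kept = []
    for edge in out.edges:
        try:
            keep = evaluate(expr, edge.attributes, strict=strict)
        except Exception as exc:
            raise type(exc)(
                f"evaluating filter on edge ({edge.source!r}, {edge.target!r}): {exc}"
            ) from exc
        if keep:
            kept.append(edge)
    out.edges = kept
    return out


def filter_nodes(
    graph: TransmissionGraph, expr: FilterExpression, strict: bool = False
) -> TransmissionGraph:
    """Keep nodes where ``expr`` is true; edges losing an endpoint go too."""
    out = graph.copy()
    kept_nodes = []
    kept_ids = set()
    for node in out.nodes:
        try:
            keep = evaluate(expr, node.attributes, strict=strict)
        except Exception as exc:
            raise type(exc)(f"evaluating filter on node {node.id!r}: {exc}") from exc
        if keep:
            kept_nodes.append(node)
            kept_ids.add(node.id)
    out.nodes = kept_nodes
    out.edges = [e for e in out.edges if e.source in kept_ids and e.target in kept_ids]
    return out


def extract_subgraph(graph: TransmissionGraph, node_ids: set[str]) -> TransmissionGraph:
    """Induced subgraph: the requested nodes plus edges internal to them.

    Attributes and definitions are preserved. Unknown ids raise
    :class:`UnknownNodeError` listing every missing id.
    """
    requested = set(node_ids)
    known = set(graph.node_ids())
    missing = sorted(requested - known)
    if missing:
        raise UnknownNodeError(f"unknown node id(s): {', '.join(missing)}")
    out = graph.copy()
    out.nodes = [n for n in out.nodes if n.id in requested]
    out.edges = [e for e in out.edges if e.source in requested and e.target in requested]
    return out


@dataclass
class ComponentLabelling:
    """A partition of the nodes into weakly-connected components.

    Component indices are contiguous from 0, assigned by decreasing
    component size with ties broken by the smallest member id, so the
    labelling is reproducible across platforms and node orderings.
    """

    labels: dict[str, int] = field(default_factory=dict)
    components: list[list[str]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.components)


def connected_components(graph: TransmissionGraph) -> ComponentLabelling:
    """Label each node with its weak-component index.

    On a distance matrix thresholded at a cutoff these components are the
    single-linkage clusters (e.g. groups linked at ≤50 SNPs).
    """
    g = to_networkx(graph)
    if graph.directed:
        raw = nx.weakly_connected_components(g)
    else:
        raw = nx.connected_components(g)
    node_order = {nid: i for i, nid in enumerate(graph.node_ids())}
    comps = [sorted(c, key=lambda nid: node_order[nid]) for c in raw]
    comps.sort(key=lambda members: (-len(members), min(members)))
    labels = {nid: idx for idx, members in enumerate(comps) for nid in members}
    return ComponentLabelling(labels=labels, components=comps)


def largest_components(graph: TransmissionGraph, n: int) -> list[TransmissionGraph]:
    """Induced subgraphs of the ``n`` largest components, size-ordered.

    Asking for more components than exist returns them all with a warning.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    labelling = connected_components(graph)
    if n > labelling.count:
        warnings.warn(
            f"requested {n} components but the graph has only {labelling.count}",
            stacklevel=2,
        )
        n = labelling.count
    return [extract_subgraph(graph, set(members)) for members in labelling.components[:n]]


def drop_isolated_nodes(graph: TransmissionGraph) -> TransmissionGraph:
    """Remove degree-0 nodes only; display hygiene after aggressive filtering."""
    out = graph.copy()
    connected: set[str] = set()
    for e in out.edges:
        connected.add(e.source)
        connected.add(e.target)
    out.nodes = [node for node in out.nodes if node.id in connected]
    return out
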