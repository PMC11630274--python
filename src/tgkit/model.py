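"""In-memory model and serialization of the trjson transmission-graph format.

A transmission graph stores sequenced isolates (nodes) and putative
transmission links between them (edges). Both carry typed attributes —
strings, integers or floating-point numbers — such as an SNP distance, a
directed transmission probability, an IBD fraction, or clinical metadata.

The on-disk format is UTF-8 JSON with ``nodes`` and ``edges`` arrays plus a
``directed`` boolean and an optional ``definitions`` array. Node objects must
carry a unique string ``id``; edge objects must carry ``source`` and
``target`` referencing node ids. Every other key on a node or edge object is
an attribute. Serialization is deterministic: insertion order for nodes and
edges, fixed key order inside each object (``id``/``source``/``target``
first, attributes sorted lexicographically), so equal graphs produce
byte-identical documents.
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

from .errors import (
    AttributeKindError,
    TrjsonParseError,
    TrjsonValidationError,
)

AttrValue = Union[str, int, float]

#: Permitted attribute kinds, in narrowing order for inference.
KINDS = ("string", "integer", "float")

_RESERVED_NODE_KEYS = frozenset({"id"})
_RESERVED_EDGE_KEYS = frozenset({"source", "target"})


def _kind_of(value: AttrValue) -> str:
    # bool is an int subclass in Python; booleans are not a permitted kind.
    if isinstance(value, bool):
        raise AttributeKindError(f"boolean attribute value {value!r} is not permitted")
    if isinstance(value, str):
        return "string"
    if isinstance(value, int):
        return "integer"
    if isinstance(value, float):
        return "float"
    raise AttributeKindError(f"unsupported attribute value {value!r} of type {type(value).__name__}")


def _is_legal_value(value: object) -> bool:
    if isinstance(value, bool):
        return False
    if isinstance(value, str):
        return True
    if isinstance(value, int):
        return True
    if isinstance(value, float):
        return math.isfinite(value)
    return False


@dataclass
class Node:
    """A sample in the transmission graph.

    ``id`` is a non-empty string, unique within a graph. ``attributes`` maps
    attribute names to string/int/float values.
    """

    id: str
    attributes: dict[str, AttrValue] = field(default_factory=dict)


@dataclass
class Edge:
    """A putative transmission link between two samples.

    ``source`` and ``target`` reference node ids; self-loops are rejected at
    validation. In an undirected graph the (source, target) order is storage
    order only.
    """

    source: str
    target: str
    attributes: dict[str, AttrValue] = field(default_factory=dict)

    def pair(self, directed: bool) -> tuple[str, str] | frozenset[str]:
        """Identity of this edge's endpoint pair under a directedness."""
        if directed:
            return (self.source, self.target)
        return frozenset((self.source, self.target))


@dataclass
class AttributeDefinition:
    """Declared name, scope and kind of an attribute, with optional prose."""

    name: str
    scope: str  # "node" | "edge"
    kind: str  # "string" | "integer" | "float"
    description: str | None = None


@dataclass
class TransmissionGraph:
    """Ordered nodes and edges with typed attributes and a directedness flag.

    Undirected graphs allow at most one edge per unordered node pair;
    directed graphs allow one per ordered pair, so up to two between a pair
    of nodes (one per direction of transmission).
    """

    directed: bool = False
    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    definitions: list[AttributeDefinition] = field(default_factory=list)

    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def node(self, node_id: str) -> Node:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def copy(self) -> "TransmissionGraph":
        return TransmissionGraph(
            directed=self.directed,
            nodes=[Node(n.id, dict(n.attributes)) for n in self.nodes],
            edges=[Edge(e.source, e.target, dict(e.attributes)) for e in self.edges],
            definitions=[
                AttributeDefinition(d.name, d.scope, d.kind, d.description)
                for d in self.definitions
            ],
        )


@dataclass
class Violation:
    rule: str
    path: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    def add(self, rule: str, path: str, message: str) -> None:
        self.violations.append(Violation(rule, path, message))

    def __str__(self) -> str:
        if self.valid:
            return "valid trjson document"
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  [{v.rule}] {v.path}: {v.message}" for v in self.violations]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# validation


def _validate_payload(doc: object) -> ValidationReport:
    """Schema-check a parsed JSON payload."""
    report = ValidationReport()
    if not isinstance(doc, dict):
        report.add("document-not-object", "$", "top-level JSON value must be an object")
        return report

    directed = doc.get("directed", False)
    if not isinstance(directed, bool):
        report.add("directed-not-boolean", "$.directed", f"expected a boolean, got {directed!r}")
        directed = False

    for key in ("nodes", "edges"):
        if key not in doc:
            report.add(f"missing-{key}", "$", f"required array {key!r} is absent")
        elif not isinstance(doc[key], list):
            report.add(f"{key}-not-array", f"$.{key}", f"{key!r} must be an array")

    nodes = doc.get("nodes") if isinstance(doc.get("nodes"), list) else []
    edges = doc.get("edges") if isinstance(doc.get("edges"), list) else []

    seen_ids: set[str] = set()
    node_attr_kinds: dict[str, set[str]] = {}
    for i, node in enumerate(nodes):
        path = f"$.nodes[{i}]"
        if not isinstance(node, dict):
            report.add("node-not-object", path, "node entries must be objects")
            continue
        nid = node.get("id")
        if not isinstance(nid, str) or not nid:
            report.add("node-id-missing", path, "node must have a non-empty string 'id'")
        elif nid in seen_ids:
            report.add("node-id-duplicate", path, f"duplicate node id {nid!r}")
        else:
            seen_ids.add(nid)
        for key, value in node.items():
            if key in _RESERVED_NODE_KEYS:
                continue
            if not _is_legal_value(value):
                report.add(
                    "attribute-kind-illegal",
                    f"{path}.{key}",
                    f"attribute values must be string, integer or float; got {value!r}",
                )
            else:
                node_attr_kinds.setdefault(key, set()).add(_kind_of(value))

    seen_pairs: set[object] = set()
    edge_attr_kinds: dict[str, set[str]] = {}
    for i, edge in enumerate(edges):
        path = f"$.edges[{i}]"
        if not isinstance(edge, dict):
            report.add("edge-not-object", path, "edge entries must be objects")
            continue
        src, tgt = edge.get("source"), edge.get("target")
        ok = True
        for role, endpoint in (("source", src), ("target", tgt)):
            if not isinstance(endpoint, str) or not endpoint:
                report.add(
                    "edge-endpoint-missing", path, f"edge must have a non-empty string {role!r}"
                )
                ok = False
            elif endpoint not in seen_ids:
                report.add(
                    "edge-endpoint-dangling",
                    path,
                    f"{role} {endpoint!r} does not reference any node id",
                )
                ok = False
        if ok and src == tgt:
            report.add("edge-self-loop", path, f"self-loop on node {src!r} is not allowed")
            ok = False
        if ok:
            pair = (src, tgt) if directed else frozenset((src, tgt))
            if pair in seen_pairs:
                kind = "ordered" if directed else "unordered"
                report.add(
                    "edge-pair-duplicate",
                    path,
                    f"more than one edge for {kind} pair ({src!r}, {tgt!r})",
                )
            else:
                seen_pairs.add(pair)
        for key, value in edge.items():
            if key in _RESERVED_EDGE_KEYS:
                continue
            if not _is_legal_value(value):
                report.add(
                    "attribute-kind-illegal",
                    f"{path}.{key}",
                    f"attribute values must be string, integer or float; got {value!r}",
                )
            else:
                edge_attr_kinds.setdefault(key, set()).add(_kind_of(value))

    definitions = doc.get("definitions", [])
    if not isinstance(definitions, list):
        report.add("definitions-not-array", "$.definitions", "'definitions' must be an array")
        definitions = []
    seen_defs: set[tuple[str, str]] = set()
    for i, d in enumerate(definitions):
        path = f"$.definitions[{i}]"
        if not isinstance(d, dict):
            report.add("definition-not-object", path, "definition entries must be objects")
            continue
        name, scope, kind = d.get("name"), d.get("scope"), d.get("kind")
        if not isinstance(name, str) or not name:
            report.add("definition-name-missing", path, "definition needs a non-empty 'name'")
            continue
        if scope not in ("node", "edge"):
            report.add("definition-scope-illegal", path, f"scope must be 'node' or 'edge', got {scope!r}")
            continue
        if kind not in KINDS:
            report.add("definition-kind-illegal", path, f"kind must be one of {KINDS}, got {kind!r}")
            continue
        if (name, scope) in seen_defs:
            report.add("definition-duplicate", path, f"duplicate definition for ({name!r}, {scope!r})")
            continue
        seen_defs.add((name, scope))
        observed = (node_attr_kinds if scope == "node" else edge_attr_kinds).get(name, set())
        for obs in observed:
            # an integer value is acceptable under a float definition
            if obs == kind or (obs == "integer" and kind == "float"):
                continue
            report.add(
                "definition-kind-mismatch",
                path,
                f"{scope} attribute {name!r} declared {kind} but holds {obs} values",
            )
    return report


def validate_document(text: str) -> ValidationReport:
    """Validate trjson text against the schema, without mutating anything.

    Returns a report listing every violation found. Unparseable JSON raises
    :class:`TrjsonParseError` — a malformed byte stream is a different
    failure from a well-formed document that breaks a schema rule.
    """
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise TrjsonParseError(f"not parseable as JSON: {exc}") from exc
    return _validate_payload(payload)


# ---------------------------------------------------------------------------
# reading / writing


def _graph_from_payload(doc: dict) -> TransmissionGraph:
    nodes = [
        Node(n["id"], {k: v for k, v in n.items() if k not in _RESERVED_NODE_KEYS})
        for n in doc.get("nodes", [])
    ]
    edges = [
        Edge(
            e["source"],
            e["target"],
            {k: v for k, v in e.items() if k not in _RESERVED_EDGE_KEYS},
        )
        for e in doc.get("edges", [])
    ]
    definitions = [
        AttributeDefinition(d["name"], d["scope"], d["kind"], d.get("description"))
        for d in doc.get("definitions", [])
    ]
    return TransmissionGraph(
        directed=doc.get("directed", False),
        nodes=nodes,
        edges=edges,
        definitions=definitions,
    )


def read_trjson(source: Union[str, os.PathLike, IO[str]]) -> TransmissionGraph:
    """Read and validate a trjson document from a path or text stream.

    Node order, edge order and attribute value kinds are preserved exactly
    as serialized; numeric-looking strings stay strings.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    report = validate_document(text)
    if not report.valid:
        raise TrjsonValidationError(f"invalid trjson document: {report}", report=report)
    return _graph_from_payload(json.loads(text))


def graph_to_payload(graph: TransmissionGraph) -> dict:
    """Serialize a graph to a JSON-ready payload with deterministic key order."""
    nodes = []
    for n in graph.nodes:
        obj: dict[str, object] = {"id": n.id}
        for key in sorted(n.attributes):
            obj[key] = n.attributes[key]
        nodes.append(obj)
    edges = []
    for e in graph.edges:
        obj = {"source": e.source, "target": e.target}
        for key in sorted(e.attributes):
            obj[key] = e.attributes[key]
        edges.append(obj)
    payload: dict[str, object] = {"directed": graph.directed}
    if graph.definitions:
        payload["definitions"] = [
            {
                "name": d.name,
                "scope": d.scope,
                "kind": d.kind,
                **({"description": d.description} if d.description is not None else {}),
            }
            for d in graph.definitions
        ]
    payload["nodes"] = nodes
    payload["edges"] = edges
    return payload


def dumps_trjson(graph: TransmissionGraph) -> str:
    """Serialize a graph to trjson text; identical graphs give identical bytes.

    Raises :class:`TrjsonValidationError` if the graph violates any type
    invariant — the writer refuses to emit an invalid document.
    """
    payload = graph_to_payload(graph)
    report = _validate_payload(payload)
    if not report.valid:
        raise TrjsonValidationError(f"graph violates trjson invariants: {report}", report=report)
    return json.dumps(payload, indent=2, ensure_ascii=False, sort_keys=False) + "\n"


def write_trjson(graph: TransmissionGraph, target: Union[str, os.PathLike, IO[str]]) -> str:
    """Write a graph as trjson to a path or text stream; returns the text."""
    text = dumps_trjson(graph)
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def loads_trjson(text: str) -> TransmissionGraph:
    """Parse trjson text (validating) into a graph."""
    return read_trjson(io.StringIO(text))


# ---------------------------------------------------------------------------
# definition inference


def _narrowest_kind(kinds: Iterable[str], name: str, scope: str) -> str:
    kinds = set(kinds)
    if kinds <= {"integer"}:
        return "integer"
    if kinds <= {"integer", "float"}:
        return "float"
    if kinds == {"string"}:
        return "string"
    raise AttributeKindError(
        f"{scope} attribute {name!r} mixes string and numeric values; kinds seen: {sorted(kinds)}"
    )


def infer_definitions(graph: TransmissionGraph) -> list[AttributeDefinition]:
    """Derive one definition per observed (attribute, scope) pair.

    The inferred kind is the narrowest kind consistent with every observed
    value (all-integer → integer; any float among numerics → float). An
    attribute mixing strings and numbers in one scope raises
    :class:`AttributeKindError` naming the attribute.
    """
    observed: dict[tuple[str, str], set[str]] = {}
    for n in graph.nodes:
        for key, value in n.attributes.items():
            observed.setdefault((key, "node"), set()).add(_kind_of(value))
    for e in graph.edges:
        for key, value in e.attributes.items():
            observed.setdefault((key, "edge"), set()).add(_kind_of(value))
    return [
        AttributeDefinition(name, scope, _narrowest_kind(kinds, name, scope))
        for (name, scope), kinds in sorted(observed.items())
    ]
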