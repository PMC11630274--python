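"""Annotation and render-ready export.

Turns an annotated transmission graph into artifacts a figure pipeline can
consume: a deterministic qualitative colour/shape styling, a seeded
force-directed layout with non-overlapping component packing, a JSON
document in the element dialect of the cytoscape web renderer, and static
PNG/SVG images with a legend.

Colour policy: a categorical attribute with at most 12 distinct values gets
one colour per value from a fixed 12-class qualitative palette, assigned in
sorted value order so figures are stable across node reorderings. Beyond 12
values no qualitative scheme is honest — recycled colours would silently
conflate categories — so every value falls back to a single neutral grey and
a warning is emitted. Individual colours can be overridden per value.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
from matplotlib.lines import Line2D

from .errors import StyleError
from .model import AttrValue, TransmissionGraph
from .ops import to_networkx

#: Fixed 12-class qualitative palette (paired hues, colourblind-considerate).
QUALITATIVE_PALETTE: tuple[str, ...] = (
    "#a6cee3", "#1f78b4", "#b2df8a", "#33a02c",
    "#fb9a99", "#e31a1c", "#fdbf6f", "#ff7f00",
    "#cab2d6", "#6a3d9a", "#ffff99", "#b15928",
)

#: Largest categorical value set that receives an automatic qualitative scheme.
MAX_QUALITATIVE_VALUES = 12

NEUTRAL_COLOUR = "#999999"
DEFAULT_NODE_COLOUR = "#888888"
DEFAULT_SHAPE = "circle"

SHAPES: tuple[str, ...] = ("circle", "square", "triangle", "diamond", "hexagon", "star")

_MPL_MARKERS = {
    "circle": "o",
    "square": "s",
    "triangle": "^",
    "diamond": "D",
    "hexagon": "h",
    "star": "*",
}

#: Default seed for layout when none is supplied.
DEFAULT_LAYOUT_SEED = 42


def _sort_key(value: AttrValue):
    # numbers sort before strings, numerically; strings lexicographically
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return (0, float(value), "")
    return (1, 0.0, str(value))


@dataclass
class StyleMap:
    """Value→colour/shape assignments plus label attribute choices."""

    colour_attribute: str | None = None
    colours: dict[AttrValue, str] = field(default_factory=dict)
    shape_attribute: str | None = None
    shapes: dict[AttrValue, str] = field(default_factory=dict)
    node_label_attribute: str | None = None
    edge_label_attribute: str | None = None
    scope: str = "node"

    def override_colour(self, value: AttrValue, colour: str) -> "StyleMap":
        """Replace one value's colour (user reassignment)."""
        self.colours[value] = colour
        return self

    def node_colour(self, attributes: Mapping[str, AttrValue]) -> str:
        if self.colour_attribute is None:
            return DEFAULT_NODE_COLOUR
        value = attributes.get(self.colour_attribute)
        return self.colours.get(value, DEFAULT_NODE_COLOUR)

    def node_shape(self, attributes: Mapping[str, AttrValue]) -> str:
        if self.shape_attribute is None:
            return DEFAULT_SHAPE
        value = attributes.get(self.shape_attribute)
        return self.shapes.get(value, DEFAULT_SHAPE)


def _distinct_values(graph: TransmissionGraph, attribute: str, scope: str) -> list[AttrValue]:
    if scope == "node":
        holders = [n.attributes for n in graph.nodes]
    elif scope == "edge":
        holders = [e.attributes for e in graph.edges]
    else:
        raise StyleError(f"scope must be 'node' or 'edge', got {scope!r}")
    values = {attrs[attribute] for attrs in holders if attribute in attrs}
    if not any(attribute in attrs for attrs in holders):
        raise StyleError(f"attribute {attribute!r} not present on any {scope}")
    return sorted(values, key=_sort_key)


def assign_palette(graph: TransmissionGraph, attribute: str, scope: str = "node") -> StyleMap:
    """Assign qualitative colours to the distinct values of an attribute.

    Up to 12 distinct values each receive a distinct palette colour, in
    sorted value order. Beyond 12 every value maps to a single neutral grey
    and a warning is emitted (no recycled colours).
    """
    values = _distinct_values(graph, attribute, scope)
    if len(values) > MAX_QUALITATIVE_VALUES:
        warnings.warn(
            f"attribute {attribute!r} has {len(values)} distinct values; "
            f"a qualitative scheme covers at most {MAX_QUALITATIVE_VALUES} — "
            "falling back to a single neutral colour",
            stacklevel=2,
        )
        colours = {value: NEUTRAL_COLOUR for value in values}
    else:
        colours = {value: QUALITATIVE_PALETTE[i] for i, value in enumerate(values)}
    return StyleMap(colour_attribute=attribute, colours=colours, scope=scope)


def assign_shapes(graph: TransmissionGraph, attribute: str, scope: str = "node",
                  style: StyleMap | None = None) -> StyleMap:
    """Assign node shapes (6 available) to an attribute's values, sorted order."""
    values = _distinct_values(graph, attribute, scope)
    if len(values) > len(SHAPES):
        raise StyleError(
            f"attribute {attribute!r} has {len(values)} distinct values; "
            f"at most {len(SHAPES)} shapes are available"
        )
    out = style if style is not None else StyleMap(scope=scope)
    out.shape_attribute = attribute
    out.shapes = {value: SHAPES[i] for i, value in enumerate(values)}
    return out


# ---------------------------------------------------------------------------
# layout


@dataclass
class LayoutResult:
    """Planar coordinates per node id, arbitrary units, all finite."""

    positions: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __getitem__(self, node_id: str) -> tuple[float, float]:
        return self.positions[node_id]


def compute_layout(graph: TransmissionGraph, seed: int = DEFAULT_LAYOUT_SEED) -> LayoutResult:
    """Seeded spring-embedding with grid packing of components.

    Each weakly-connected component is laid out independently with a
    force-directed (Fruchterman–Reingold) embedding, normalised to a unit
    box, then packed onto a grid by decreasing component size with padding,
    so component bounding boxes never overlap. Identical (graph, seed)
    inputs give identical coordinates.
    """
    g = to_networkx(graph)
    ug = g.to_undirected() if graph.directed else g
    node_order = {nid: i for i, nid in enumerate(graph.node_ids())}
    comps = [sorted(c, key=lambda nid: node_order[nid]) for c in nx.connected_components(ug)]
    comps.sort(key=lambda members: (-len(members), min(members, default="")))

    positions: dict[str, tuple[float, float]] = {}
    if not comps:
        return LayoutResult(positions)

    ncols = max(1, math.ceil(math.sqrt(len(comps))))
    cell = 2.4  # unit box + padding
    for idx, members in enumerate(comps):
        sub = ug.subgraph(members)
        if len(members) == 1:
            local = {members[0]: np.zeros(2)}
        else:
            local = nx.spring_layout(sub, seed=seed + idx, dim=2)
            xs = np.array([local[m] for m in members])
            span = xs.max(axis=0) - xs.min(axis=0)
            span[span == 0] = 1.0
            centre = (xs.max(axis=0) + xs.min(axis=0)) / 2
            # normalise to a box of half-width 1 centred at the origin
            local = {m: (local[m] - centre) / span * 2.0 for m in members}
        ox = (idx % ncols) * cell
        oy = -(idx // ncols) * cell
        for m in members:
            x, y = float(local[m][0]) + ox, float(local[m][1]) + oy
            positions[m] = (x, y)
    return LayoutResult(positions)


# ---------------------------------------------------------------------------
# render document (cytoscape element dialect)


def _label_text(attributes: Mapping[str, AttrValue], attribute: str | None,
                fallback: str | None = None) -> str | None:
    if attribute is None:
        return fallback
    value = attributes.get(attribute)
    if value is None:
        return fallback
    return str(value)


def export_render_document(
    graph: TransmissionGraph, style: StyleMap, layout: LayoutResult
) -> str:
    """Emit the graph as JSON in the cytoscape web renderer's element dialect.

    One element per node (with position and resolved colour/shape/label)
    and one per edge (with resolved label). The document carries the
    directedness flag so the renderer draws arrows from the source on
    directed graphs. Output is deterministic.
    """
    for attr, scope in ((style.colour_attribute, "colour"), (style.shape_attribute, "shape")):
        if attr is not None:
            holders = graph.nodes if style.scope == "node" else graph.edges
            if not any(attr in h.attributes for h in holders):
                raise StyleError(f"{scope} attribute {attr!r} not present on the graph")
    node_elements = []
    for node in graph.nodes:
        x, y = layout[node.id]
        data: dict[str, object] = {
            "id": node.id,
            "color": style.node_colour(node.attributes),
            "shape": style.node_shape(node.attributes),
        }
        label = _label_text(node.attributes, style.node_label_attribute, fallback=node.id)
        data["label"] = label
        for key in sorted(node.attributes):
            data.setdefault(key, node.attributes[key])
        node_elements.append({"data": data, "position": {"x": x, "y": y}})
    edge_elements = []
    for i, edge in enumerate(graph.edges):
        data = {"id": f"e{i}", "source": edge.source, "target": edge.target}
        label = _label_text(edge.attributes, style.edge_label_attribute)
        if label is not None:
            data["label"] = label
        for key in sorted(edge.attributes):
            data.setdefault(key, edge.attributes[key])
        edge_elements.append({"data": data})
    document = {
        "directed": graph.directed,
        "elements": {"nodes": node_elements, "edges": edge_elements},
    }
    return json.dumps(document, indent=2, ensure_ascii=False) + "\n"


# ---------------------------------------------------------------------------
# static images


def export_image(
    graph: TransmissionGraph,
    style: StyleMap,
    layout: LayoutResult,
    path: str,
    resolution: int = 300,
) -> None:
    """Render the graph to PNG (raster, ``resolution`` dpi) or SVG by extension.

    Nodes sit at their layout positions with resolved colours and shapes;
    a legend block maps colours (and shapes) back to attribute values.
    SVG output is byte-deterministic for identical inputs.
    """
    plt.rcParams["svg.hashsalt"] = "tgkit"
    fig, ax = plt.subplots(figsize=(8, 6))
    ax.set_axis_off()

    for edge in graph.edges:
        x0, y0 = layout[edge.source]
        x1, y1 = layout[edge.target]
        if graph.directed:
            ax.annotate(
                "",
                xy=(x1, y1),
                xytext=(x0, y0),
                arrowprops=dict(arrowstyle="-|>", color="#555555", lw=0.8,
                                shrinkA=6, shrinkB=6),
            )
        else:
            ax.plot([x0, x1], [y0, y1], color="#555555", lw=0.8, zorder=1)
        if style.edge_label_attribute is not None:
            label = _label_text(edge.attributes, style.edge_label_attribute)
            if label is not None:
                ax.text((x0 + x1) / 2, (y0 + y1) / 2, label, fontsize=6,
                        ha="center", va="center", color="#333333")

    # draw nodes grouped by marker so matplotlib batches scatter calls
    by_marker: dict[str, list[tuple[float, float, str, str]]] = {}
    for node in graph.nodes:
        x, y = layout[node.id]
        colour = style.node_colour(node.attributes)
        shape = style.node_shape(node.attributes)
        by_marker.setdefault(shape, []).append((x, y, colour, node.id))
    for shape in sorted(by_marker):
        entries = by_marker[shape]
        ax.scatter(
            [e[0] for e in entries],
            [e[1] for e in entries],
            c=[e[2] for e in entries],
            marker=_MPL_MARKERS[shape],
            s=120,
            edgecolors="#333333",
            linewidths=0.6,
            zorder=2,
        )
    if style.node_label_attribute is not None or graph.nodes:
        for node in graph.nodes:
            label = _label_text(node.attributes, style.node_label_attribute,
                                fallback=node.id)
            x, y = layout[node.id]
            ax.text(x, y - 0.12, label, fontsize=6, ha="center", va="top",
                    color="#111111", zorder=3)

    handles = []
    if style.colour_attribute is not None:
        for value in sorted(style.colours, key=_sort_key):
            handles.append(
                Line2D([], [], marker="o", linestyle="", markersize=8,
                       markerfacecolor=style.colours[value],
                       markeredgecolor="#333333",
                       label=f"{style.colour_attribute} = {value}")
            )
    if style.shape_attribute is not None:
        for value in sorted(style.shapes, key=_sort_key):
            handles.append(
                Line2D([], [], marker=_MPL_MARKERS[style.shapes[value]],
                       linestyle="", markersize=8, markerfacecolor="#cccccc",
                       markeredgecolor="#333333",
                       label=f"{style.shape_attribute} = {value}")
            )
    legend_title = "Legend"
    ax.legend(handles=handles, loc="upper left", bbox_to_anchor=(1.0, 1.0),
              fontsize=7, title=legend_title, title_fontsize=8, frameon=True)

    save_kwargs: dict[str, object] = {"bbox_inches": "tight"}
    if path.lower().endswith(".svg"):
        save_kwargs["metadata"] = {"Date": None}
    else:
        save_kwargs["dpi"] = resolution
    fig.savefig(path, **save_kwargs)
    plt.close(fig)
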