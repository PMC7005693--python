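"""Pathway-diagram expression overlay with binned colouring.

Nodes of a signal-transduction pathway graph (genes or gene categories) are
coloured by the per-cell-type median expression, expressed as
log2(median RPKM + 1), on a fixed 0-15 window divided into 20 equal bins.
Category nodes (diagram boxes standing for several genes) take the maximum
of their members' values. Exports carry bin indices and raw values per cell
type rather than colours, leaving the palette to the renderer, plus
per-member boxplot payloads — the static equivalent of clicking a pathway
member in the interactive viewer.
"""

from __future__ import annotations

import json
import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .expression import (
    BoxStats,
    ExpressionMatrix,
    LineageMedianTable,
    ScaleError,
    boxplot_stats,
)

logger = logging.getLogger(__name__)

NODE_TYPES = ("gene_product", "category", "non_gene")

#: Colour window on the log2(RPKM + 1) scale, and its bin count.
DEFAULT_RANGE = (0.0, 15.0)
DEFAULT_N_BINS = 20


class PathwaySchemaError(ValueError):
    """The pathway file violates the schema."""


@dataclass
class PathwayNode:
    id: str
    label: str
    members: list[str]
    node_type: str


@dataclass
class PathwayGraph:
    pathway_id: str
    title: str
    nodes: dict[str, PathwayNode]
    edges: list[tuple[str, str, str]]  # (source, target, interaction label)

    def validate(self) -> None:
        for node in self.nodes.values():
            if node.node_type not in NODE_TYPES:
                raise PathwaySchemaError(
                    f"node {node.id!r}: unknown node_type {node.node_type!r}"
                )
            if node.node_type == "gene_product" and len(node.members) != 1:
                raise PathwaySchemaError(
                    f"node {node.id!r}: gene_product nodes need exactly one member"
                )
            if node.node_type == "category" and len(node.members) < 2:
                raise PathwaySchemaError(
                    f"node {node.id!r}: category nodes need at least two members"
                )
        for src, tgt, _label in self.edges:
            for endpoint in (src, tgt):
                if endpoint not in self.nodes:
                    raise PathwaySchemaError(
                        f"edge ({src!r} -> {tgt!r}) references missing node {endpoint!r}"
                    )


def load_pathway(path) -> PathwayGraph:
    """Load the native JSON pathway schema (see docs/methods.md)."""
    payload = json.loads(Path(path).read_text())
    nodes: dict[str, PathwayNode] = {}
    for entry in payload.get("nodes", []):
        node_id = str(entry["id"])
        if node_id in nodes:
            raise PathwaySchemaError(f"duplicate node id {node_id!r}")
        members = [str(m).upper() for m in entry.get("members", [])]
        node_type = entry.get("type", "gene_product")
        if node_type != "non_gene" and not members:
            raise PathwaySchemaError(f"node {node_id!r}: gene nodes need members")
        nodes[node_id] = PathwayNode(
            id=node_id,
            label=str(entry.get("label", node_id)),
            members=members,
            node_type=node_type,
        )
    edges = [
        (str(e["source"]), str(e["target"]), str(e.get("interaction", "")))
        for e in payload.get("edges", [])
    ]
    graph = PathwayGraph(
        pathway_id=str(payload.get("pathway_id", Path(path).stem)),
        title=str(payload.get("title", "")),
        nodes=nodes,
        edges=edges,
    )
    graph.validate()
    return graph


def write_pathway(graph: PathwayGraph, path) -> None:
    payload = {
        "pathway_id": graph.pathway_id,
        "title": graph.title,
        "nodes": [
            {
                "id": n.id,
                "label": n.label,
                "type": n.node_type,
                "members": n.members,
            }
            for n in graph.nodes.values()
        ],
        "edges": [
            {"source": s, "target": t, "interaction": lbl} for s, t, lbl in graph.edges
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_kgml(path) -> PathwayGraph:
    """Import a KGML subset: ``entry`` elements of type gene (first graphics
    alias as the symbol) and group (components become category members), and
    ``relation`` elements as edges. Compound mapping and coordinates are
    ignored."""
    root = ET.parse(path).getroot()
    nodes: dict[str, PathwayNode] = {}
    first_symbol: dict[str, str] = {}
    for entry in root.findall("entry"):
        etype = entry.get("type", "")
        eid = entry.get("id", "")
        graphics = entry.find("graphics")
        if etype == "gene":
            gname = (graphics.get("name") or eid) if graphics is not None else eid
            symbol = gname.split(",")[0].strip().rstrip(".").upper()
            first_symbol[eid] = symbol
            nodes[eid] = PathwayNode(eid, symbol, [symbol], "gene_product")
        elif etype == "group":
            components = [c.get("id", "") for c in entry.findall("component")]
            nodes[eid] = PathwayNode(eid, f"group:{eid}", components, "category")
        else:
            label = (graphics.get("name") or eid) if graphics is not None else eid
            nodes[eid] = PathwayNode(eid, label, [], "non_gene")
    # resolve group components (entry ids) to their gene symbols
    for node in nodes.values():
        if node.node_type == "category":
            symbols = [first_symbol[c] for c in node.members if c in first_symbol]
            if len(symbols) < 2:
                node.node_type = "gene_product" if len(symbols) == 1 else "non_gene"
            node.members = symbols
    edges = []
    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1", ""), rel.get("entry2", "")
        subtypes = ";".join(s.get("name", "") for s in rel.findall("subtype"))
        if e1 in nodes and e2 in nodes:
            edges.append((e1, e2, subtypes))
    graph = PathwayGraph(
        pathway_id=root.get("name", Path(path).stem),
        title=root.get("title", ""),
        nodes=nodes,
        edges=edges,
    )
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# Colouring
# ---------------------------------------------------------------------------

def bin_value(
    v: float,
    value_range: tuple[float, float] = DEFAULT_RANGE,
    n_bins: int = DEFAULT_N_BINS,
) -> int:
    """Map a log2(RPKM + 1) value to a bin index in {0, ..., n_bins - 1}.

    Bins are half-open [k*w, (k+1)*w) of width w = range / n_bins, with the
    top bin closed: values at or above the window top clamp to the last bin.
    """
    lo, hi = value_range
    if hi <= lo or n_bins < 2:
        raise ValueError("value range must be increasing and n_bins >= 2")
    width = (hi - lo) / n_bins
    clamped = min(max(v, lo), hi)
    return min(int(math.floor((clamped - lo) / width)), n_bins - 1)


@dataclass
class NodeColouring:
    """Per-node overlay values and bins for one cell type."""

    cell_type: str
    values: dict[str, float] = field(default_factory=dict)
    bins: dict[str, int] = field(default_factory=dict)
    value_range: tuple[float, float] = DEFAULT_RANGE
    n_bins: int = DEFAULT_N_BINS


def colour_nodes(
    pathway: PathwayGraph,
    medians: LineageMedianTable,
    cell_type: str,
    value_range: tuple[float, float] = DEFAULT_RANGE,
    n_bins: int = DEFAULT_N_BINS,
) -> NodeColouring:
    """Colour gene and category nodes by median expression in one cell type.

    Gene nodes take v = log2(median RPKM + 1); category nodes take the
    maximum over their members' values; genes absent from the median table
    count as median 0 with a warning. Non-gene nodes stay uncoloured.
    """
    if medians.scale != "rpkm":
        raise ScaleError(f"median table on scale {medians.scale!r}; RPKM required")
    if cell_type not in medians.values.columns:
        raise ValueError(f"unknown cell type {cell_type!r}")
    table = medians.values[cell_type]

    def member_value(gene: str) -> float:
        if gene not in table.index:
            logger.warning("gene %s absent from medians; treated as median 0", gene)
            return 0.0
        return float(np.log2(table.loc[gene] + 1.0))

    colouring = NodeColouring(cell_type=cell_type, value_range=value_range, n_bins=n_bins)
    for node in pathway.nodes.values():
        if node.node_type == "non_gene":
            continue
        values = [member_value(g) for g in node.members]
        v = max(values)
        colouring.values[node.id] = v
        colouring.bins[node.id] = bin_value(v, value_range, n_bins)
    return colouring


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def overlay_to_nx(pathway: PathwayGraph, colourings: list[NodeColouring]) -> nx.DiGraph:
    graph = nx.DiGraph(pathway_id=pathway.pathway_id, title=pathway.title)
    for node in pathway.nodes.values():
        attrs = {
            "label": node.label,
            "node_type": node.node_type,
            "members": ";".join(node.members),
        }
        for colouring in colourings:
            if node.id in colouring.values:
                attrs[f"value_{colouring.cell_type}"] = colouring.values[node.id]
                attrs[f"bin_{colouring.cell_type}"] = colouring.bins[node.id]
        graph.add_node(node.id, **attrs)
    for src, tgt, label in pathway.edges:
        graph.add_edge(src, tgt, interaction=label)
    return graph


def export_overlay(
    pathway: PathwayGraph,
    colourings: list[NodeColouring],
    matrix: ExpressionMatrix,
    graphml_path,
    boxplot_path,
) -> nx.DiGraph:
    """Write the annotated GraphML and the per-node boxplot payload JSON.

    The boxplot payload lists, for every gene/category node, one BoxStats per
    member gene per lineage (category nodes get per-member boxplots, not a
    pooled one), computed from the given matrix on its own scale.
    """
    graph = overlay_to_nx(pathway, colourings)
    nx.write_graphml(graph, graphml_path)

    payload: dict[str, dict] = {}
    lineages = matrix.lineages()
    for node in pathway.nodes.values():
        if node.node_type == "non_gene":
            continue
        node_payload: dict[str, dict] = {}
        for gene in node.members:
            if gene not in matrix.gene_ids:
                continue
            per_lineage = {}
            for lin in lineages:
                vals = matrix.values.loc[gene, matrix.cells_of(lin)]
                per_lineage[lin] = boxplot_stats(vals).as_dict()
            node_payload[gene] = per_lineage
        payload[node.id] = node_payload
    Path(boxplot_path).write_text(json.dumps(
        {"pathway_id": pathway.pathway_id, "scale": matrix.scale, "nodes": payload},
        indent=2,
        sort_keys=True,
    ))
    return graph


def load_overlay(graphml_path) -> nx.DiGraph:
    """Read an exported overlay back (round-trip checks, renderers)."""
    return nx.read_graphml(graphml_path)
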