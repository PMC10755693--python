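"""Sequence similarity networks: construction, centrality-guided threshold
selection, clustering, and annotated export.

An SSN places proteins as nodes and retains an edge wherever the pairwise
alignment score (AS, −log10 of an E-value-like quantity) meets a threshold.
As the threshold rises the network fragments into clusters that, at a
well-chosen threshold, approximate isofunctional groups.  The threshold is
chosen here by a concrete centrality-guided criterion: take the smallest AS
at which the cluster count sits on a plateau *and* the mean betweenness has
collapsed relative to its value at the loosest threshold — inter-family
bridge edges are exactly the edges that carry betweenness, so their
disappearance marks family separation.  The full sweep table is always
returned so a human can re-select.

Betweenness is unnormalised (raw pair counts) internally; normalised values
appear only in exported reports.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from sqgsuite.pairalign import ScoredPair

#: deterministic colour cycle for export annotation
PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
)


@dataclass
class SSNGraph:
    """A thresholded similarity network with deterministic cluster numbering."""

    graph: nx.Graph
    threshold: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def clusters(self) -> list[frozenset[str]]:
        """Connected components ordered by (size desc, lexicographic min id)."""
        comps = [frozenset(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), min(c)))

    def cluster_of(self) -> dict[str, int]:
        """Node → 1-based cluster number under the deterministic ordering."""
        out = {}
        for num, comp in enumerate(self.clusters(), start=1):
            for node in comp:
                out[node] = num
        return out


def build_graph(
    edges: Sequence[ScoredPair],
    threshold: float,
    nodes: Iterable[str] | None = None,
) -> SSNGraph:
    """Retain edges with AS ≥ threshold; nodes with no surviving edge stay in
    the graph as singletons (all edge endpoints are nodes; ``nodes`` may add
    further isolated records)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    g = nx.Graph()
    for e in edges:
        g.add_node(e.id_a)
        g.add_node(e.id_b)
        if e.id_a != e.id_b and e.alignment_score_AS >= threshold:
            g.add_edge(e.id_a, e.id_b,
                       AS=float(e.alignment_score_AS),
                       pct_id=float(e.percent_identity))
    if nodes is not None:
        g.add_nodes_from(nodes)
    return SSNGraph(g, threshold)


def centrality_profile(ssn: SSNGraph) -> pd.DataFrame:
    """Exact per-node degree, betweenness (unnormalised), closeness and
    eigenvector centralities (eigenvector computed per component)."""
    g = ssn.graph
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    betw = nx.betweenness_centrality(g, normalized=False)
    close = nx.closeness_centrality(g)
    eig: dict[str, float] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges() == 0:
            for n in comp:
                eig[n] = 1.0
        else:
            eig.update(nx.eigenvector_centrality_numpy(sub))
    rows = [{
        "node": n,
        "degree": g.degree(n),
        "betweenness": betw[n],
        "closeness": close[n],
        "eigenvector": eig[n],
    } for n in sorted(g.nodes)]
    return pd.DataFrame(rows).set_index("node")


@dataclass
class ThresholdSweep:
    """The sweep table behind centrality-guided threshold selection."""

    table: pd.DataFrame  # threshold, n_clusters, n_singletons, mean_degree,
    #                      mean_betweenness
    selected: float | None
    status: str  # "ok" | "no plateau found"


def select_threshold(
    sweep_grid: Sequence[float],
    edges: Sequence[ScoredPair],
    strategy: str = "auto",
    collapse_fraction: float = 0.1,
    nodes: Iterable[str] | None = None,
) -> ThresholdSweep:
    """Sweep AS thresholds and pick one by plateau + betweenness collapse.

    The default strategy selects the smallest grid AS at which (a) the
    cluster count is unchanged over at least two consecutive grid steps and
    (b) the mean betweenness is below ``collapse_fraction`` of its value at
    the grid minimum.  When the baseline betweenness is already zero, (b)
    degenerates to requiring zero betweenness on a graph that still has
    edges.  ``strategy="manual"`` emits the sweep table without selecting.
    """
    grid = sorted(float(t) for t in sweep_grid)
    if len(grid) < 3:
        raise ValueError("sweep grid needs at least 3 points")
    if len(set(grid)) != len(grid):
        raise ValueError("sweep grid must be strictly increasing")
    nodes = list(nodes) if nodes is not None else None

    rows = []
    graphs = []
    for t in grid:
        ssn = build_graph(edges, t, nodes=nodes)
        g = ssn.graph
        n_nodes = g.number_of_nodes()
        betw = (nx.betweenness_centrality(g, normalized=False)
                if n_nodes else {})
        rows.append({
            "threshold": t,
            "n_clusters": nx.number_connected_components(g),
            "n_singletons": sum(1 for n in g if g.degree(n) == 0),
            "mean_degree": (2.0 * g.number_of_edges() / n_nodes
                            if n_nodes else 0.0),
            "mean_betweenness": (float(np.mean(list(betw.values())))
                                 if betw else 0.0),
            "n_edges": g.number_of_edges(),
        })
        graphs.append(g)
    table = pd.DataFrame(rows)

    if strategy == "manual":
        return ThresholdSweep(table, None, "manual")
    if strategy != "auto":
        raise ValueError(f"unknown strategy {strategy!r}")

    counts = table["n_clusters"].to_numpy()
    betw_mean = table["mean_betweenness"].to_numpy()
    baseline = betw_mean[0]
    selected = None
    for i in range(len(grid)):
        # plateau: unchanged over >= 2 consecutive grid steps from i
        if i + 2 >= len(grid):
            break
        if not (counts[i] == counts[i + 1] == counts[i + 2]):
            continue
        if baseline > 0:
            collapsed = betw_mean[i] < collapse_fraction * baseline
        else:
            collapsed = (betw_mean[i] == 0.0
                         and graphs[i].number_of_edges() > 0)
        if collapsed:
            selected = grid[i]
            break
    status = "ok" if selected is not None else "no plateau found"
    return ThresholdSweep(table, selected, status)


# --- annotation and export -------------------------------------------------

def _color_map(labels: Sequence[str]) -> dict[str, str]:
    uniq = sorted(set(labels))
    return {lab: PALETTE[i % len(PALETTE)] for i, lab in enumerate(uniq)}


def annotate(
    ssn: SSNGraph,
    metadata: pd.DataFrame | Mapping[str, Mapping[str, str]],
    scheme: str = "taxonomy",
) -> SSNGraph:
    """Attach per-node label/colour attributes from a metadata table.

    ``scheme`` picks the metadata column: ``taxonomy`` or
    ``pathway-context`` (column ``pathway_context``).  Nodes missing from
    the table are labelled ``unannotated``.
    """
    if scheme not in ("taxonomy", "pathway-context"):
        raise ValueError(f"unknown scheme {scheme!r}")
    col = "taxonomy" if scheme == "taxonomy" else "pathway_context"
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.DataFrame.from_dict(metadata, orient="index")
    if metadata.index.has_duplicates:
        dupes = metadata.index[metadata.index.duplicated()].tolist()
        raise ValueError(f"metadata id collisions: {dupes}")
    labels = {
        n: (str(metadata.loc[n, col])
            if n in metadata.index and pd.notna(metadata.loc[n, col])
            else "unannotated")
        for n in ssn.graph.nodes
    }
    colors = _color_map(list(labels.values()))
    cluster = ssn.cluster_of()
    for n in ssn.graph.nodes:
        ssn.graph.nodes[n]["label"] = labels[n]
        ssn.graph.nodes[n]["color"] = colors[labels[n]]
        ssn.graph.nodes[n]["cluster"] = cluster[n]
    return ssn


def write_graphml(ssn: SSNGraph, path: str | Path) -> None:
    nx.write_graphml(ssn.graph, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


_XGMML_NS = "http://www.cs.rpi.edu/XGMML"


def write_xgmml(ssn: SSNGraph, path: str | Path, label: str = "SSN") -> None:
    """Cytoscape-dialect XGMML with node colour/label attributes."""
    root = ET.Element("graph", {
        "label": label, "directed": "0", "xmlns": _XGMML_NS,
    })
    ids = {n: str(i) for i, n in enumerate(sorted(ssn.graph.nodes))}
    for n in sorted(ssn.graph.nodes):
        node_el = ET.SubElement(root, "node", {"id": ids[n], "label": str(n)})
        for key, val in sorted(ssn.graph.nodes[n].items()):
            t = "real" if isinstance(val, float) else (
                "integer" if isinstance(val, (int, np.integer)) else "string")
            ET.SubElement(node_el, "att",
                          {"name": key, "value": str(val), "type": t})
    for a, b, data in sorted(ssn.graph.edges(data=True)):
        edge_el = ET.SubElement(root, "edge", {
            "source": ids[a], "target": ids[b], "label": f"{a}--{b}",
        })
        for key, val in sorted(data.items()):
            t = "real" if isinstance(val, float) else (
                "integer" if isinstance(val, (int, np.integer)) else "string")
            ET.SubElement(edge_el, "att",
                          {"name": key, "value": str(val), "type": t})
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), xml_declaration=True, encoding="unicode")


def read_xgmml(path: str | Path) -> nx.Graph:
    """Read back an XGMML file written by :func:`write_xgmml` losslessly."""
    tree = ET.parse(str(path))
    root = tree.getroot()
    ns = {"x": _XGMML_NS}
    g = nx.Graph()
    id_to_label = {}

    def parse_att(el):
        t, v = el.get("type", "string"), el.get("value")
        if t == "real":
            return float(v)
        if t == "integer":
            return int(v)
        return v

    for node_el in root.findall("x:node", ns):
        label = node_el.get("label")
        id_to_label[node_el.get("id")] = label
        attrs = {a.get("name"): parse_att(a)
                 for a in node_el.findall("x:att", ns)}
        g.add_node(label, **attrs)
    for edge_el in root.findall("x:edge", ns):
        a = id_to_label[edge_el.get("source")]
        b = id_to_label[edge_el.get("target")]
        attrs = {at.get("name"): parse_att(at)
                 for at in edge_el.findall("x:att", ns)}
        g.add_edge(a, b, **attrs)
    return g


def annotate_and_export(
    ssn: SSNGraph,
    metadata: pd.DataFrame | Mapping[str, Mapping[str, str]],
    scheme: str,
    xgmml_path: str | Path | None = None,
    graphml_path: str | Path | None = None,
) -> SSNGraph:
    """Annotate by the chosen scheme and write XGMML and/or GraphML."""
    ssn = annotate(ssn, metadata, scheme)
    if xgmml_path is not None:
        write_xgmml(ssn, xgmml_path)
    if graphml_path is not None:
        write_graphml(ssn, graphml_path)
    return ssn
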