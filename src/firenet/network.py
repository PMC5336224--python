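"""Directed weighted wildfire-transmission networks.

Nodes are land tenures (and, at the finer scale, individual communities);
a directed edge i -> j carries the annual area ignited in i that burned
in j. Self-loops (non-transmitted fire) are excluded: the diagonal of the
transmission matrix is reported separately, not as an edge. Density and
degree follow the usual simple-digraph definitions.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .transmission import TransmissionMatrix

__all__ = [
    "build_network",
    "network_density",
    "node_degrees",
    "out_strength_ranking",
    "export_network",
]

#: default edge filters (ha/yr): tenure-scale figure threshold, community
#: scale threshold, and the lower "dashed" display band
EDGE_MIN_TENURE = 20.0
EDGE_MIN_COMMUNITY = 10.0
EDGE_MIN_DASHED = 1.0


def build_network(
    matrix: TransmissionMatrix | pd.DataFrame,
    min_edge: float = 0.0,
    node_class: dict[str, str] | None = None,
) -> nx.DiGraph:
    """Directed graph with an edge i -> j wherever M[i][j] > min_edge.

    The node set always includes every matrix label, even isolates, so
    density reflects the full landscape. Edge weights are ha/yr.
    """
    if min_edge < 0:
        raise ValueError("min_edge must be >= 0")
    m = matrix.matrix if isinstance(matrix, TransmissionMatrix) else matrix
    g = nx.DiGraph()
    for label in m.index:
        cls = (node_class or {}).get(label,
                                     "community" if str(label).startswith("community:")
                                     else "tenure")
        g.add_node(label, node_class=cls)
    for src in m.index:
        for dst in m.columns:
            if src != dst and m.loc[src, dst] > min_edge:
                g.add_edge(src, dst, weight=float(m.loc[src, dst]))
    return g


def network_density(net: nx.DiGraph) -> float:
    """E / (N (N-1)) for a simple directed graph without self-loops."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("density requires >= 2 nodes")
    return net.number_of_edges() / (n * (n - 1))


def node_degrees(net: nx.DiGraph) -> pd.DataFrame:
    """Per-node in-degree, out-degree and total degree."""
    rows = {
        node: (net.in_degree(node), net.out_degree(node))
        for node in net.nodes
    }
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["in_degree", "out_degree"])
    df["degree"] = df["in_degree"] + df["out_degree"]
    return df.sort_index()


def out_strength_ranking(net: nx.DiGraph) -> pd.Series:
    """Nodes ranked by weighted out-strength (summed outgoing ha/yr).

    Used as the centrality measure: the simplest weight-sum index of how
    much fire a tenure exports.
    """
    strength = {
        node: sum(d["weight"] for _, _, d in net.out_edges(node, data=True))
        for node in net.nodes
    }
    return pd.Series(strength).sort_values(ascending=False)


def export_network(net: nx.DiGraph, edge_csv, graphml=None, node_csv=None) -> None:
    """Write edge list CSV, optional GraphML and node attribute table."""
    edges = pd.DataFrame(
        [(u, v, d["weight"]) for u, v, d in net.edges(data=True)],
        columns=["source", "destination", "ha_per_yr"],
    )
    edges.to_csv(edge_csv, index=False)
    if graphml is not None:
        nx.write_graphml(net, graphml)
    if node_csv is not None:
        deg = node_degrees(net)
        deg["node_class"] = [net.nodes[n].get("node_class", "") for n in deg.index]
        deg["out_strength"] = out_strength_ranking(net).reindex(deg.index)
        deg.to_csv(node_csv, index_label="node")
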