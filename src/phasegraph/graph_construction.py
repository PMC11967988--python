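"""Molecule-level contact graphs under periodic boundary conditions.

Two molecules are joined by an (undirected, unweighted) edge when at least
one pair of their tail sites lies strictly closer than the cutoff distance,
measured with the minimum-image convention.  Neighbour search uses a
periodic k-d tree (cell-list equivalent); the result is identical to the
all-pairs brute force.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .particles import (
    DEFAULT_CUTOFF,
    DEFAULT_SELECTION,
    ConfigurationError,
    ParticleConfiguration,
    SelectionSpec,
    minimum_image,
    wrap_positions,
)

__all__ = [
    "build_contact_graph",
    "connected_components",
    "export_graph",
    "import_graph",
]


def build_contact_graph(
    config: ParticleConfiguration,
    selection: SelectionSpec = DEFAULT_SELECTION,
    cutoff: float = DEFAULT_CUTOFF,
) -> nx.Graph:
    """Build the contact graph of a configuration.

    Nodes are molecule ids of all molecules owning at least one site with a
    role in ``selection.tail_roles`` (for ``node_scope="atom"`` every selected
    site is its own node).  An edge (i, j) exists iff the minimum over all
    selected-site pairs of molecules i != j of the periodic minimum-image
    distance is strictly below ``cutoff``.

    The cutoff must satisfy ``0 < cutoff < min(box)/2`` for the minimum-image
    convention to be valid.
    """
    box = config.box
    if not (0.0 < cutoff < float(np.min(box)) / 2.0):
        raise ConfigurationError(
            f"cutoff must lie in (0, min(box)/2) = (0, {np.min(box) / 2:.3f}) nm"
        )
    mask = config.select(selection.tail_roles)
    if not mask.any():
        raise ConfigurationError(
            f"selection {sorted(selection.tail_roles)} matches no sites"
        )
    pos = wrap_positions(config.positions[mask], box)
    if selection.node_scope == "atom":
        node_of_site = np.arange(mask.sum())
    else:
        node_of_site = config.molecule_id[mask]

    # Periodic k-d tree; boxsize requires coordinates inside [0, box).
    tree = cKDTree(np.minimum(pos, np.nextafter(box, 0.0)), boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")

    graph = nx.Graph()
    graph.add_nodes_from(np.unique(node_of_site).tolist())
    if len(pairs):
        # enforce the *strict* inequality: drop pairs at exactly the cutoff
        delta = minimum_image(pos[pairs[:, 0]] - pos[pairs[:, 1]], box)
        dist = np.linalg.norm(delta, axis=1)
        pairs = pairs[dist < cutoff]
        a = node_of_site[pairs[:, 0]]
        b = node_of_site[pairs[:, 1]]
        keep = a != b
        edges = {(min(i, j), max(i, j)) for i, j in zip(a[keep], b[keep])}
        graph.add_edges_from(edges)
    graph.graph["cutoff"] = cutoff
    graph.graph["time"] = config.time
    return graph


def connected_components(graph: nx.Graph) -> list[set]:
    """Connected components as a disjoint cover of all nodes (largest first)."""
    return sorted(nx.connected_components(graph), key=len, reverse=True)


def export_graph(graph: nx.Graph, path, format: str = "edge_list") -> None:
    """Serialize a graph as a two-column edge list or as GraphML.

    The edge list holds one ``i j`` pair per line (isolated nodes are kept in
    GraphML only); node ids are stable across a round trip.
    """
    path = Path(path)
    if format == "edge_list":
        nx.write_edgelist(graph, path, data=False)
    elif format == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ConfigurationError(f"unknown graph format {format!r}")


def import_graph(path, format: str = "edge_list") -> nx.Graph:
    """Read a graph written by :func:`export_graph` (integer node ids)."""
    path = Path(path)
    if format == "edge_list":
        return nx.read_edgelist(path, nodetype=int, data=False)
    if format == "graphml":
        g = nx.read_graphml(path)
        return nx.relabel_nodes(g, {n: int(n) for n in g.nodes})
    raise ConfigurationError(f"unknown graph format {format!r}")
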