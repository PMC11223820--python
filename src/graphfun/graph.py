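"""Residue-level radius graph construction.

Residues are nodes; a directed edge pair (j, i) and (i, j) exists for every
unordered residue pair whose C-alpha distance is strictly below the cutoff
(15 A by default).  The node's own contribution to message passing
("N(i) union i") is handled inside the network layer, not as a self-loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import ProteinRecord

DEFAULT_CUTOFF = 15.0


@dataclass
class ProteinGraph:
    """Radius-graph topology plus assembled node/edge feature matrices.

    ``edges`` is an (E, 2) integer array of directed (source j, target i)
    pairs, sorted by (target, source).  Feature matrices are filled in by
    :func:`graphfun.features.assemble_graph`.
    """

    n_nodes: int
    edges: np.ndarray
    ca_coords: np.ndarray
    node_features: np.ndarray | None = None
    edge_features: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def validate(self) -> None:
        if self.edges.size:
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("graph contains self-loops")
            fwd = {tuple(e) for e in self.edges}
            if {(i, j) for j, i in fwd} != fwd:
                raise ValueError("directed edge set is not symmetric")
        if self.node_features is not None and len(self.node_features) != self.n_nodes:
            raise ValueError("node feature row count != n_nodes")
        if self.edge_features is not None and len(self.edge_features) != self.n_edges:
            raise ValueError("edge feature row count != n_edges")


def build_radius_graph(record: ProteinRecord, cutoff: float = DEFAULT_CUTOFF) -> ProteinGraph:
    """Build the radius-graph topology for a protein.

    Edges connect residue pairs with C-alpha distance strictly less than
    ``cutoff`` (ties at exactly the cutoff are excluded); both directions are
    present and ordered by (target, source).
    """
    if len(record) == 0:
        raise ValueError("cannot build a graph from an empty record")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca = record.ca_coords()
    n = len(ca)
    pairs = cKDTree(ca).query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(ca[pairs[:, 0]] - ca[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]  # strict inequality at the cutoff
    if len(pairs):
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])
        dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
        edges = np.stack([src, dst], axis=1)
        order = np.lexsort((edges[:, 0], edges[:, 1]))  # sort by (target, source)
        edges = edges[order]
    else:
        edges = np.zeros((0, 2), dtype=np.int64)
    graph = ProteinGraph(n_nodes=n, edges=edges.astype(np.int64), ca_coords=ca)
    graph.validate()
    return graph


def export_edge_list(graph: ProteinGraph, path) -> None:
    """Debug export: TSV of (source, target, CA-CA distance)."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tdistance\n")
        for j, i in graph.edges:
            d = float(np.linalg.norm(graph.ca_coords[j] - graph.ca_coords[i]))
            fh.write(f"{j}\t{i}\t{d:.4f}\n")
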