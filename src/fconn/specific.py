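"""Assembly and export of "specific networks".

A specific network keeps only the nodes of one sign's significant clusters
and the FDR-significant edges internal to that node set — the subgraph that
summarises where the group difference lives.  Hubs are ranked by
within-network degree (ties broken by atlas index).  Export formats follow
BrainNet Viewer conventions: a ``.node`` file with six whitespace-separated
columns (x, y, z, colour code, size, label) and a ``.edge`` file holding
the full dense symmetric weight matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import NodeCluster, POSITIVE, NEGATIVE
from .io import RegionTable

#: BrainNet colour codes: one constant per sign (cosmetic, configurable).
SIGN_COLOR = {POSITIVE: 1.0, NEGATIVE: 2.0}


@dataclass
class SpecificNetwork:
    """Significant-cluster nodes joined by FDR-significant edges."""

    sign: str
    nodes: list  # sorted node indices
    edges: list  # (i, j) pairs, i < j, both endpoints in nodes
    n_regions: int = 0

    def __post_init__(self):
        node_set = set(self.nodes)
        for i, j in self.edges:
            if i not in node_set or j not in node_set:
                raise ValueError(f"edge ({i}, {j}) has an endpoint outside the node set")

    @property
    def degree(self) -> dict:
        deg = {n: 0 for n in self.nodes}
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    @property
    def hubs(self) -> list:
        """Nodes by descending within-network degree; ties by atlas index."""
        deg = self.degree
        return sorted(self.nodes, key=lambda n: (-deg[n], n))

    def summary(self) -> dict:
        return {
            "sign": self.sign,
            "n_nodes": len(self.nodes),
            "n_edges": len(self.edges),
            "nodes": [int(n) for n in self.nodes],
            "edges": [[int(i), int(j)] for i, j in self.edges],
            "hubs": [int(n) for n in self.hubs],
        }


def build_specific_network(
    clusters: list[NodeCluster], sign: str, edge_mask: np.ndarray
) -> SpecificNetwork:
    """Induce the significant-edge subgraph on one sign's cluster nodes.

    ``edge_mask`` is the dense symmetric 0/1 significance matrix from the
    edge-wise FDR analysis.  A sign with no clusters yields an empty
    network (not an error).
    """
    edge_mask = np.asarray(edge_mask)
    if edge_mask.ndim != 2 or edge_mask.shape[0] != edge_mask.shape[1]:
        raise ValueError("edge mask must be square")
    if not np.array_equal(edge_mask, edge_mask.T):
        raise ValueError("edge mask must be symmetric")
    nodes = sorted({n for c in clusters if c.sign == sign for n in c.members})
    if nodes and max(nodes) >= edge_mask.shape[0]:
        raise ValueError("cluster node index outside edge-mask dimension")
    node_set = set(nodes)
    edges = [
        (i, j)
        for i, j in zip(*np.triu_indices(edge_mask.shape[0], k=1))
        if edge_mask[i, j] and i in node_set and j in node_set
    ]
    return SpecificNetwork(
        sign=sign,
        nodes=nodes,
        edges=[(int(i), int(j)) for i, j in edges],
        n_regions=edge_mask.shape[0],
    )


def export_brainnet(net: SpecificNetwork, regions: RegionTable, node_path, edge_path) -> None:
    """Write BrainNet Viewer ``.node`` and ``.edge`` files for a network."""
    if len(regions) < net.n_regions:
        raise ValueError("region table smaller than the network's region count")
    xyz = regions.coordinates
    labels = regions.labels
    deg = net.degree
    color = SIGN_COLOR.get(net.sign, 1.0)
    with open(node_path, "w") as fh:
        for n in net.nodes:
            x, y, z = xyz[n]
            fh.write(f"{x:g} {y:g} {z:g} {color:g} {deg[n]:g} {labels[n]}\n")
    full = np.zeros((net.n_regions, net.n_regions))
    for i, j in net.edges:
        full[i, j] = full[j, i] = 1.0
    with open(edge_path, "w") as fh:
        for row in full:
            fh.write("\t".join(f"{v:g}" for v in row) + "\n")


def read_brainnet(node_path, edge_path, regions: RegionTable, sign: str) -> SpecificNetwork:
    """Parse BrainNet files back into a :class:`SpecificNetwork` (round-trip)."""
    label_to_idx = {lab: k for k, lab in enumerate(regions.labels)}
    nodes = []
    with open(node_path) as fh:
        for ln in fh:
            parts = ln.split()
            if parts:
                nodes.append(label_to_idx[parts[5]])
    full = np.loadtxt(edge_path, delimiter="\t", ndmin=2)
    rows, cols = np.nonzero(np.triu(full, k=1))
    edges = [(int(i), int(j)) for i, j in zip(rows, cols)]
    return SpecificNetwork(sign=sign, nodes=sorted(nodes), edges=edges, n_regions=full.shape[0])
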