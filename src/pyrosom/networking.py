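"""Fragmentation-spectrum molecular networking with class propagation.

Nodes are consensus spectra of aligned features; candidate edges are pairs
with cosine similarity >= a threshold (default 0.7), and an edge survives
only if each endpoint ranks the other within its TopK (default 10) most
similar candidate neighbors — mutual TopK, which is the only pruning rule
that guarantees "maximum number of neighboring nodes per node" = K. Nodes
left without edges are singletons and are excluded from cluster output.

Compound classes propagate from library-annotated nodes to unannotated
neighbors: each unclassified node takes the class of its most similar,
connected, originally-annotated neighbor, in a single pass by default
(propagated labels do not chain unless explicitly enabled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import AlignedFeature
from .annotation import UNCLASSIFIED, Annotation
from .errors import ParameterError
from .similarity import cosine_matrix
from .spectra_io import Spectrum


@dataclass
class NetworkNode:
    """One molecular-network node with its annotation and abundances."""

    node_id: str
    spectrum: Spectrum
    annotation: Annotation
    abundance: dict[str, float] = field(default_factory=dict)

    @property
    def compound_class(self) -> str:
        return self.annotation.compound_class

    @property
    def total_abundance(self) -> float:
        return float(sum(self.abundance.values()))


@dataclass
class MolecularNetwork:
    """Pruned cosine-similarity graph over consensus spectra."""

    nodes: dict[str, NetworkNode]
    edges: list[tuple[str, str, float]]
    min_cosine: float
    topk: int
    #: class labels after propagation; provenance "library" | "propagated"
    classes: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.classes:
            for nid, node in self.nodes.items():
                self.classes[nid] = node.compound_class
                if node.compound_class != UNCLASSIFIED:
                    self.provenance[nid] = "library"

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges, weight="cosine")
        return g

    def degree(self, node_id: str) -> int:
        return sum(1 for a, b, _ in self.edges if node_id in (a, b))

    @property
    def singletons(self) -> set[str]:
        connected = {n for a, b, _ in self.edges for n in (a, b)}
        return set(self.nodes) - connected

    def neighbors(self, node_id: str) -> list[tuple[str, float]]:
        out = []
        for a, b, c in self.edges:
            if a == node_id:
                out.append((b, c))
            elif b == node_id:
                out.append((a, c))
        return out


def _mutual_topk_edges(
    ids: Sequence[str], sim: np.ndarray, min_cosine: float, topk: int
) -> list[tuple[str, str, float]]:
    """Edges >= min_cosine kept iff each endpoint is in the other's TopK."""
    n = len(ids)
    candidate = [
        [j for j in range(n) if j != i and sim[i, j] >= min_cosine]
        for i in range(n)
    ]
    # rank candidates by similarity desc, index asc for deterministic ties
    topsets: list[set[int]] = []
    for i in range(n):
        ranked = sorted(candidate[i], key=lambda j: (-sim[i, j], j))
        topsets.append(set(ranked[:topk]))
    edges = []
    for i in range(n):
        for j in topsets[i]:
            if j > i and i in topsets[j]:
                edges.append((ids[i], ids[j], float(sim[i, j])))
    return edges


def build_network(
    nodes: Sequence[AlignedFeature],
    annotations: Sequence[Annotation],
    min_cosine: float = 0.7,
    topk: int = 10,
    abundance: Mapping[str, Mapping[str, float]] | None = None,
) -> MolecularNetwork:
    """Build the mutual-TopK molecular network.

    ``abundance`` optionally maps node_id -> {group label -> abundance}
    (e.g. per-ecosystem summed heights); it defaults to each aligned
    feature's per-sample heights.
    """
    if not 0 < min_cosine <= 1:
        raise ParameterError("min_cosine must be in (0, 1]")
    if topk < 1:
        raise ParameterError("topk must be >= 1")
    ann_by_id = {a.node_id: a for a in annotations}
    net_nodes: dict[str, NetworkNode] = {}
    for nf in nodes:
        ann = ann_by_id.get(nf.node_id, Annotation(nf.node_id))
        ab = (dict(abundance[nf.node_id]) if abundance is not None
              and nf.node_id in abundance else dict(nf.per_sample_height))
        net_nodes[nf.node_id] = NetworkNode(nf.node_id, nf.consensus_spectrum,
                                            ann, ab)
    if len(nodes) < 2:
        return MolecularNetwork(net_nodes, [], min_cosine, topk)
    ids = [nf.node_id for nf in nodes]
    sim = cosine_matrix([nf.consensus_spectrum for nf in nodes])
    edges = _mutual_topk_edges(ids, sim, min_cosine, topk)
    return MolecularNetwork(net_nodes, edges, min_cosine, topk)


def clusters(net: MolecularNetwork) -> list[set[str]]:
    """Connected components of the pruned graph, singletons excluded.

    Ordered by size descending, then by smallest member node_id.
    """
    g = net.graph()
    g.remove_nodes_from(net.singletons)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def propagate_classes(
    net: MolecularNetwork, chain: bool = False, max_rounds: int = 100
) -> MolecularNetwork:
    """Assign classes to unclassified nodes from annotated neighbors.

    Single pass (default): every unclassified node with at least one
    originally-classified neighbor takes the class of its highest-cosine
    such neighbor; ties go to the higher total-abundance neighbor, then the
    lexicographically smaller node_id. Originally classified nodes never
    change; nodes with no classified neighbor stay unclassified. With
    ``chain=True`` passes repeat, letting freshly propagated labels seed
    further propagation, until a fixed point.
    """
    classes = dict(net.classes)
    provenance = dict(net.provenance)
    sources = {nid for nid, cls in classes.items() if cls != UNCLASSIFIED}
    rounds = max_rounds if chain else 1
    for _ in range(rounds):
        updates: dict[str, str] = {}
        for nid in net.nodes:
            if classes[nid] != UNCLASSIFIED:
                continue
            nbrs = [(other, cos) for other, cos in net.neighbors(nid)
                    if other in sources]
            if not nbrs:
                continue
            nbrs.sort(key=lambda t: (
                -t[1], -net.nodes[t[0]].total_abundance, t[0]))
            updates[nid] = classes[nbrs[0][0]]
        if not updates:
            break
        for nid, cls in updates.items():
            classes[nid] = cls
            provenance[nid] = "propagated"
        if not chain:
            break
        sources |= set(updates)
    return MolecularNetwork(net.nodes, net.edges, net.min_cosine, net.topk,
                            classes, provenance)


@dataclass
class EcosystemDistribution:
    """Per-node ecosystem abundance shares and presence breadth counts."""

    shares: pd.DataFrame                 # nodes x ecosystems, rows sum to 1
    presence_counts: dict[int, int]      # k ecosystems -> number of nodes
    zero_abundance_nodes: list[str]      # flagged, excluded from shares

    def exclusive_nodes(self, ecosystems: Sequence[str]) -> list[str]:
        """Nodes whose abundance lies entirely within the given ecosystems."""
        eco = set(ecosystems)
        out = []
        for nid, row in self.shares.iterrows():
            present = {c for c, v in row.items() if v > 0}
            if present and present <= eco:
                out.append(str(nid))
        return out


def ecosystem_distribution(
    net: MolecularNetwork,
    ecosystem_of: Mapping[str, str] | None = None,
) -> EcosystemDistribution:
    """Relative abundance of each node across ecosystems.

    Node abundances are grouped by ``ecosystem_of`` (sample -> ecosystem;
    identity when the node abundances are already per-ecosystem), then
    normalized per node to shares summing to 1. Also counts how many nodes
    are present (share > 0) in exactly k ecosystems. Nodes with zero total
    abundance are flagged and excluded from the share table.
    """
    rows: dict[str, dict[str, float]] = {}
    zero: list[str] = []
    for nid, node in sorted(net.nodes.items()):
        acc: dict[str, float] = {}
        for key, val in node.abundance.items():
            eco = ecosystem_of.get(key, key) if ecosystem_of else key
            acc[eco] = acc.get(eco, 0.0) + float(val)
        total = sum(acc.values())
        if total <= 0:
            zero.append(nid)
            continue
        rows[nid] = {k: v / total for k, v in acc.items()}
    shares = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    shares = shares.reindex(sorted(shares.columns), axis=1)
    counts: dict[int, int] = {}
    for _, row in shares.iterrows():
        k = int((row > 0).sum())
        counts[k] = counts.get(k, 0) + 1
    return EcosystemDistribution(shares, counts, zero)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_edge_list(net: MolecularNetwork, path: str | Path) -> None:
    """Tab-separated edge list: node_a, node_b, cosine."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tcosine\n")
        for a, b, c in sorted(net.edges):
            fh.write(f"{a}\t{b}\t{c:.6f}\n")


def write_graphml(net: MolecularNetwork, path: str | Path) -> None:
    """GraphML with class, provenance and compound attributes per node."""
    g = nx.Graph()
    for nid, node in net.nodes.items():
        g.add_node(
            nid,
            compound=node.annotation.compound or "",
            compound_class=net.classes.get(nid, UNCLASSIFIED),
            provenance=net.provenance.get(nid, ""),
            total_abundance=node.total_abundance,
        )
    for a, b, c in net.edges:
        g.add_edge(a, b, cosine=c)
    nx.write_graphml(g, str(path))
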