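"""The merged gene–metabolite global interaction network.

A single undirected simple graph whose nodes are genes or metabolites.
Each node carries a *prize* — the absolute log2 fold change of the
measured feature, 0 for nodes never quantified — and each edge a
confidence in (0, 1] from which a traversal cost is derived
(cost = 1 − confidence).  A degree-proportional hub penalty can be
subtracted from prizes to discourage the Steiner forest from swallowing
highly connected nodes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

NODE_TYPES = ("gene", "metabolite")

__all__ = [
    "InteractionNetwork",
    "read_network",
    "merge_networks",
    "assign_prizes",
    "apply_hub_penalty",
    "edge_costs_from_confidence",
]


class InteractionNetwork:
    """Typed, prized, undirected simple graph over genes and metabolites.

    Thin wrapper around :class:`networkx.Graph`; node attributes are
    ``node_type`` ("gene"|"metabolite"), ``prize`` (>= 0, the adjusted
    prize used by the solver), ``raw_prize`` (before hub penalty),
    ``measured`` (bool); edge attributes ``confidence`` in (0, 1] and
    ``cost`` >= 0.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction -------------------------------------------------
    def add_node(self, node_id: str, node_type: str, prize: float = 0.0, measured: bool = False):
        if node_type not in NODE_TYPES:
            raise ValueError(f"node type for {node_id!r} must be one of {NODE_TYPES}")
        if node_id in self.graph and self.graph.nodes[node_id]["node_type"] != node_type:
            raise ValueError(
                f"node {node_id!r} already present with conflicting type "
                f"{self.graph.nodes[node_id]['node_type']!r} vs {node_type!r}"
            )
        self.graph.add_node(
            node_id, node_type=node_type, prize=float(prize), raw_prize=float(prize), measured=measured
        )

    def add_edge(self, u: str, v: str, confidence: float):
        if u == v:
            raise ValueError(f"self-loop on {u!r} not allowed")
        if not 0 < confidence <= 1:
            raise ValueError(f"confidence for edge {u!r}-{v!r} must be in (0, 1], got {confidence}")
        for x in (u, v):
            if x not in self.graph:
                raise ValueError(f"edge endpoint {x!r} is not a node")
        if self.graph.has_edge(u, v):
            confidence = max(confidence, self.graph.edges[u, v]["confidence"])
        self.graph.add_edge(u, v, confidence=float(confidence))

    # -- accessors -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def node_type(self, v: str) -> str:
        return self.graph.nodes[v]["node_type"]

    def prize(self, v: str) -> float:
        return self.graph.nodes[v]["prize"]

    def cost(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["cost"]

    def gene_nodes(self) -> set[str]:
        return {v for v, d in self.graph.nodes(data=True) if d["node_type"] == "gene"}

    def metabolite_nodes(self) -> set[str]:
        return {v for v, d in self.graph.nodes(data=True) if d["node_type"] == "metabolite"}

    def total_prize(self) -> float:
        return sum(d["prize"] for _, d in self.graph.nodes(data=True))

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.copy())

    def induced(self, nodes) -> nx.Graph:
        """Induced subgraph of the global network over a node subset."""
        return self.graph.subgraph(nodes).copy()

    # -- io -------------------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str, float]],
        node_types: dict[str, str],
    ) -> "InteractionNetwork":
        net = cls()
        for node_id in sorted(node_types):
            net.add_node(node_id, node_types[node_id])
        for u, v, conf in edges:
            net.add_edge(u, v, conf)
        return net

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for _, d in g.nodes(data=True):
            d["measured"] = bool(d.get("measured", False))
        nx.write_graphml(g, path)


def read_network(edge_path: str | Path, node_type_path: str | Path) -> InteractionNetwork:
    """Load a network from an edge-list TSV (u, v, confidence) and a node-type TSV."""
    types = pd.read_csv(node_type_path, sep="\t", header=None, names=["node_id", "node_type"], dtype=str)
    edges = pd.read_csv(
        edge_path, sep="\t", header=None, names=["u", "v", "confidence"],
        dtype={"u": str, "v": str, "confidence": float},
    )
    return InteractionNetwork.from_edges(
        list(edges.itertuples(index=False, name=None)),
        dict(zip(types["node_id"], types["node_type"])),
    )


def merge_networks(a: InteractionNetwork, b: InteractionNetwork) -> InteractionNetwork:
    """Union of two networks; duplicate edges keep the maximum confidence.

    A node id shared between the inputs must carry the same type in both —
    a gene in one and a metabolite in the other is an identifier clash.
    """
    merged = InteractionNetwork()
    for net in (a, b):
        for v in net.nodes():
            merged.add_node(v, net.node_type(v))  # raises on type conflict
    for net in (a, b):
        for u, v, d in net.graph.edges(data=True):
            merged.add_edge(u, v, d["confidence"])  # max rule inside add_edge
    return merged


def assign_prizes(
    net: InteractionNetwork,
    stats: pd.DataFrame,
    significant_only: bool = False,
    prize_floor: float = 0.0,
) -> InteractionNetwork:
    """Set node prizes from multi-omics differential statistics.

    A node measured in one or more layers receives the maximum |log2FC|
    across those layers; nodes never measured keep prize 0 and
    ``measured = False``.  Features absent from the network are counted
    and logged, never added.

    ``significant_only`` restricts prizes to features with a positive
    significance call; ``prize_floor`` zeroes prizes below an effect-size
    threshold (prizes at noise scale otherwise let the forest absorb
    large parts of a well-connected network).
    """
    out = net.copy()
    table = stats[stats["significant"]] if significant_only else stats
    missing = 0
    best: dict[str, float] = {}
    for fid, lfc in zip(table["feature_id"], table["log2fc"]):
        if fid not in out.graph:
            missing += 1
            continue
        best[fid] = max(best.get(fid, 0.0), abs(float(lfc)))
    for v in out.graph.nodes:
        prize = best.get(v, 0.0)
        if prize < prize_floor:
            prize = 0.0
        out.graph.nodes[v]["prize"] = prize
        out.graph.nodes[v]["raw_prize"] = prize
        out.graph.nodes[v]["measured"] = v in best
    if missing:
        logger.warning("%d measured features were absent from the network", missing)
    return out


def apply_hub_penalty(net: InteractionNetwork, mu: float = 0.01) -> InteractionNetwork:
    """Reduce each prize by mu × degree, clamped at 0; raw prizes are retained."""
    if mu < 0:
        raise ValueError("hub penalty mu must be >= 0")
    out = net.copy()
    for v in out.graph.nodes:
        d = out.graph.nodes[v]
        d["prize"] = max(0.0, d["raw_prize"] - mu * out.graph.degree(v))
    return out


def edge_costs_from_confidence(net: InteractionNetwork) -> InteractionNetwork:
    """Derive traversal costs: cost(e) = 1 − confidence(e) ∈ [0, 1)."""
    out = net.copy()
    for u, v, d in out.graph.edges(data=True):
        conf = d["confidence"]
        if not 0 < conf <= 1:
            raise ValueError(f"confidence out of (0, 1] on edge {u!r}-{v!r}: {conf}")
        d["cost"] = 1.0 - conf
    return out
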