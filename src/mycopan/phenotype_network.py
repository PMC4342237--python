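"""Phenotype network reconstruction and the connection-strength statistic.

Each categorical phenotype value observed in a strain table becomes a node
whose members are the strains carrying that value.  Two nodes from
*different* attributes are joined by an undirected edge whenever they share
at least one member strain; nodes of the same attribute partition the
strains and are therefore never adjacent.  Edge weight is the connection
strength

    CS(Gx, Gy) = [rho(Gx) + rho(Gy)] * 50

where rho(Gx) = |Gx ∩ Gy| / |Gx| is the fraction of Gx's members shared
with Gy.  CS is symmetric, lies in [0, 100], equals 100 exactly for
identical member sets and 0 exactly for disjoint ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .data_model import PhenotypeTable, PHENOTYPE_ATTRIBUTES
from .errors import ValidationError

__all__ = [
    "PhenotypeNode",
    "PhenotypeNetwork",
    "NODE_LABELS",
    "build_network",
    "connection_strength",
    "node_degree",
    "hub_nodes",
    "degree_stats",
]

#: Display labels for phenotype values, matching the field's usual naming.
NODE_LABELS = {
    ("lifestyle", "FL"): "FL",
    ("lifestyle", "FHA"): "FHA",
    ("lifestyle", "OI"): "OI",
    ("growth_rate", "fast"): "Fast-growing",
    ("growth_rate", "slow"): "Slow-growing",
    ("pathogenicity", "pathogenic"): "Pathogenic",
    ("pathogenicity", "non-pathogenic"): "Non-pathogenic",
    ("pah_metabolism", "degrading"): "PAH-degrading",
    ("pah_metabolism", "non-degrading"): "PAH-non-degrading",
}


@dataclass(frozen=True)
class PhenotypeNode:
    """One phenotype category with its member strains."""

    name: str
    attribute: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"phenotype node {self.name!r} has no members")

    @property
    def size(self) -> int:
        return len(self.members)


def connection_strength(gx: PhenotypeNode, gy: PhenotypeNode) -> float:
    """CS(Gx, Gy) = [|Gx∩Gy|/|Gx| + |Gx∩Gy|/|Gy|] * 50, in [0, 100]."""
    shared = len(gx.members & gy.members)
    rho_x = shared / len(gx.members)
    rho_y = shared / len(gy.members)
    return (rho_x + rho_y) * 50.0


@dataclass(frozen=True)
class PhenotypeNetwork:
    """Undirected phenotype network with CS-weighted edges."""

    graph: nx.Graph

    def node(self, name: str) -> PhenotypeNode:
        if name not in self.graph:
            raise ValidationError(f"unknown phenotype node: {name!r}")
        return self.graph.nodes[name]["node"]

    @property
    def node_names(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges as (node1, node2, CS), sorted for determinism."""
        out = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, data["cs"]))
        return sorted(out)

    def cs(self, name_x: str, name_y: str) -> float:
        """Connection strength between two named nodes (0 if no edge)."""
        gx, gy = self.node(name_x), self.node(name_y)
        if gx.attribute == gy.attribute and name_x != name_y:
            return 0.0
        return connection_strength(gx, gy)


def build_network(phenotypes: PhenotypeTable,
                  attributes: Sequence[str] = PHENOTYPE_ATTRIBUTES,
                  ) -> PhenotypeNetwork:
    """Build the phenotype network over the given attributes.

    One node per observed attribute value; an edge joins every
    cross-attribute pair of nodes sharing at least one strain, weighted by
    :func:`connection_strength`.
    """
    attributes = list(attributes)
    if len(attributes) < 2:
        raise ValidationError("at least two attributes are required")
    nodes: list[PhenotypeNode] = []
    for attr in attributes:
        for value in phenotypes.values_of(attr):
            members = phenotypes.group(attr, value)
            label = NODE_LABELS.get((attr, value), f"{attr}={value}")
            nodes.append(PhenotypeNode(label, attr, frozenset(members)))
    graph = nx.Graph()
    for n in nodes:
        graph.add_node(n.name, node=n, size=n.size, attribute=n.attribute)
    for i, gx in enumerate(nodes):
        for gy in nodes[i + 1:]:
            if gx.attribute == gy.attribute:
                continue  # same-attribute nodes partition the strains
            shared = gx.members & gy.members
            if shared:
                graph.add_edge(gx.name, gy.name,
                               cs=connection_strength(gx, gy),
                               shared=len(shared))
    return PhenotypeNetwork(graph)


def node_degree(net: PhenotypeNetwork, name: str) -> int:
    """Number of edges incident to a node."""
    net.node(name)  # raises on unknown node
    return int(net.graph.degree[name])


def hub_nodes(net: PhenotypeNetwork) -> frozenset[str]:
    """All nodes attaining the maximum degree (ties all returned)."""
    if not net.graph.nodes:
        raise ValidationError("network has no nodes")
    degrees = dict(net.graph.degree)
    top = max(degrees.values())
    return frozenset(n for n, d in degrees.items() if d == top)


def degree_stats(edges: Iterable[tuple[str, str]]
                 ) -> dict[str, tuple[int, int]]:
    """Per-node (in-degree, out-degree) of a directed edge list.

    Duplicate edges are collapsed; a self-loop counts in both degrees and
    emits a warning.
    """
    seen: set[tuple[str, str]] = set()
    nodes: dict[str, list[int]] = {}
    for u, v in edges:
        nodes.setdefault(u, [0, 0])
        nodes.setdefault(v, [0, 0])
        if (u, v) in seen:
            continue
        seen.add((u, v))
        if u == v:
            warnings.warn(f"self-loop on node {u!r} counted in both degrees",
                          stacklevel=2)
        nodes[u][1] += 1
        nodes[v][0] += 1
    return {n: (d[0], d[1]) for n, d in nodes.items()}
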