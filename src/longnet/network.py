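"""Interactome assembly and longevity-network construction.

The longevity network is built from a curated "core" of known
longevity-associated genes (LAGs) by a three-step rule: keep the core genes
that have reported protein-protein interactions, add all of their
first-order interaction partners, and take the largest connected component
of the induced subgraph.  Partner-partner edges inside the candidate node
set are retained (induced-subgraph semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .io import AnnotatedGeneSet, DataError, EdgeRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Interactome:
    """Simple undirected PPI graph over canonical gene ids."""

    graph: nx.Graph
    species: str = ""

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene)

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def edge_set(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.graph.edges())


@dataclass(frozen=True)
class LongevityNetwork:
    """Core LAGs plus first-order partners, restricted to one component."""

    core_nodes: frozenset[str]
    partner_nodes: frozenset[str]
    edges: frozenset[frozenset[str]]
    parent: Interactome | None = None

    def __post_init__(self) -> None:
        if self.core_nodes & self.partner_nodes:
            raise DataError("core and partner node sets must be disjoint")

    @property
    def nodes(self) -> frozenset[str]:
        return self.core_nodes | self.partner_nodes

    @property
    def n_nodes(self) -> int:
        return len(self.core_nodes) + len(self.partner_nodes)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.core_nodes:
            g.add_node(n, role="core")
        for n in self.partner_nodes:
            g.add_node(n, role="partner")
        for e in self.edges:
            a, b = sorted(e)
            g.add_edge(a, b)
        return g

    def report(self) -> dict:
        return {
            "core_retained": len(self.core_nodes),
            "partners": len(self.partner_nodes),
            "total": self.n_nodes,
            "edges": len(self.edges),
        }


def build_interactome(records: Iterable[EdgeRecord], species: str = "") -> Interactome:
    """Assemble a simple graph: self-loops removed, reversed duplicates collapsed."""
    g = nx.Graph()
    n_loops = 0
    n_records = 0
    for rec in records:
        n_records += 1
        if rec.gene_a == rec.gene_b:
            n_loops += 1
            continue
        g.add_edge(rec.gene_a, rec.gene_b)
    if n_records == 0:
        raise DataError("no edge records supplied")
    if g.number_of_edges() == 0:
        raise DataError("empty graph: every record was a self-loop")
    if n_loops:
        logger.info("build_interactome: removed %d self-loops", n_loops)
    return Interactome(graph=g, species=species)


def _component_key(component: frozenset[str], core: set[str]) -> tuple:
    # larger first by size, then by core count, then lexicographically
    # smallest sorted node list wins among exact ties
    return (-len(component), -len(component & core), sorted(component))


def build_longevity_network(
    interactome: Interactome, core: AnnotatedGeneSet
) -> LongevityNetwork:
    """Three-step construction: core-with-PPIs, first-order partners, largest
    connected component of the induced subgraph."""
    if not core.genes:
        raise DataError("core gene set is empty")
    core_present = set(core.genes) & interactome.nodes
    if not core_present:
        raise DataError("no core gene has interactions in this interactome")
    candidates = set(core_present)
    for g in core_present:
        candidates |= interactome.neighbors(g)
    sub = interactome.graph.subgraph(candidates)
    components = [frozenset(c) for c in nx.connected_components(sub)]
    best = min(components, key=lambda c: _component_key(c, core_present))
    kept = sub.subgraph(best)
    core_kept = frozenset(best & core_present)
    partners = frozenset(best - core_present)
    net = LongevityNetwork(
        core_nodes=core_kept,
        partner_nodes=partners,
        edges=frozenset(frozenset(e) for e in kept.edges()),
        parent=interactome,
    )
    # every partner entered the candidate set as a neighbor of some core gene
    for p in net.partner_nodes:
        assert interactome.neighbors(p) & net.core_nodes, (
            f"partner {p} has no core neighbor"
        )
    logger.info(
        "longevity network: %d core, %d partners, %d nodes total",
        len(core_kept), len(partners), net.n_nodes,
    )
    return net


def coverage_fraction(
    network: LongevityNetwork, core: AnnotatedGeneSet, interactome: Interactome
) -> float:
    """Fraction of interactome-present core genes retained in the network."""
    denom = len(set(core.genes) & interactome.nodes)
    if denom == 0:
        raise DataError("no core genes present in the interactome")
    return len(network.core_nodes) / denom
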