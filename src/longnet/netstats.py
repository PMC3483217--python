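"""Degree and interconnectivity statistics with a permutation null.

Interconnectivity of a gene set is the fraction of its interactome-present
members that have at least one edge to a *different* member.  Significance
is assessed against randomized gene sets of the same size (same number of
interactome-present members), drawn either uniformly over interactome
nodes or within degree bins, with an add-one empirical p-value so p is
never exactly zero:  p = (1 + #{null >= observed}) / (1 + n_permutations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import DataError
from .network import Interactome


@dataclass(frozen=True)
class InterconnectivityResult:
    set_size: int
    n_present: int
    n_interconnected: int

    @property
    def fraction(self) -> float:
        return self.n_interconnected / self.n_present


@dataclass(frozen=True)
class PermutationNull:
    n_permutations: int
    null_fractions: tuple[float, ...]
    observed: float
    p_value: float
    seed: int
    sampling_mode: str


def interconnectivity(interactome: Interactome, genes: Iterable[str]) -> InterconnectivityResult:
    genes = set(genes)
    present = genes & interactome.nodes
    if not present:
        raise DataError("no member of the gene set is present in the interactome")
    n_inter = sum(
        1 for g in present if interactome.neighbors(g) & (present - {g})
    )
    return InterconnectivityResult(
        set_size=len(genes), n_present=len(present), n_interconnected=n_inter
    )


def _interconnected_count(adj: dict[str, set[str]], members: Sequence[str]) -> int:
    mset = set(members)
    count = 0
    for g in members:
        if adj[g] & mset:
            # adjacency sets exclude self (simple graph), so any hit is a
            # different member
            count += 1
    return count


def _degree_bins(nodes: list[str], interactome: Interactome, n_bins: int = 10):
    degrees = np.array([interactome.degree(n) for n in nodes])
    quantiles = np.quantile(degrees, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(quantiles)
    bin_idx = np.searchsorted(edges, degrees, side="left")
    bins: dict[int, list[str]] = {}
    for node, idx in zip(nodes, bin_idx):
        bins.setdefault(int(idx), []).append(node)
    node_bin = {n: int(i) for n, i in zip(nodes, bin_idx)}
    return bins, node_bin


def permutation_null(
    interactome: Interactome,
    genes: Iterable[str],
    n_permutations: int = 999,
    seed: int = 0,
    sampling_mode: str = "uniform",
) -> PermutationNull:
    """Randomized-gene-set null for interconnectivity.

    Identical (seed, inputs) give bit-identical results: node order is fixed
    by sorting before any draw.
    """
    if sampling_mode not in ("uniform", "degree_matched"):
        raise DataError(f"unknown sampling_mode {sampling_mode!r}")
    if n_permutations < 1:
        raise DataError("n_permutations must be >= 1")
    obs = interconnectivity(interactome, genes)
    if obs.n_present < 2:
        raise DataError("need at least 2 interactome-present members")
    nodes = sorted(interactome.nodes)
    if obs.n_present > len(nodes):
        raise DataError("gene set larger than the interactome")
    adj = {n: set(interactome.graph.neighbors(n)) for n in nodes}
    rng = np.random.default_rng(seed)
    k = obs.n_present
    nulls = np.empty(n_permutations)
    if sampling_mode == "uniform":
        node_arr = np.array(nodes)
        for i in range(n_permutations):
            draw = rng.choice(node_arr, size=k, replace=False)
            nulls[i] = _interconnected_count(adj, draw.tolist()) / k
    else:
        bins, node_bin = _degree_bins(nodes, interactome)
        present = sorted(set(genes) & interactome.nodes)
        need = {b: 0 for b in bins}
        for g in present:
            need[node_bin[g]] += 1
        bin_arrays = {b: np.array(sorted(members)) for b, members in bins.items()}
        for i in range(n_permutations):
            draw: list[str] = []
            for b in sorted(need):
                if need[b]:
                    picked = rng.choice(bin_arrays[b], size=need[b], replace=False)
                    draw.extend(picked.tolist())
            nulls[i] = _interconnected_count(adj, draw) / k
    p = (1 + int(np.sum(nulls >= obs.fraction))) / (1 + n_permutations)
    return PermutationNull(
        n_permutations=n_permutations,
        null_fractions=tuple(float(x) for x in nulls),
        observed=obs.fraction,
        p_value=p,
        seed=seed,
        sampling_mode=sampling_mode,
    )


@dataclass(frozen=True)
class DegreeSummary:
    mean: float
    median: float
    max: int
    degrees: dict[str, int]
    absent: frozenset[str]


def degree_summary(interactome: Interactome, genes: Iterable[str] | None = None) -> DegreeSummary:
    """Degree statistics on the simple graph, whole interactome by default.

    Members absent from the interactome are reported but excluded from the
    summary statistics.
    """
    if genes is None:
        members = sorted(interactome.nodes)
        absent: frozenset[str] = frozenset()
    else:
        genes = set(genes)
        members = sorted(genes & interactome.nodes)
        absent = frozenset(genes - interactome.nodes)
    if not members:
        raise DataError("no interactome-present genes to summarize")
    degs = {g: interactome.degree(g) for g in members}
    vals = np.array(list(degs.values()))
    return DegreeSummary(
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        max=int(vals.max()),
        degrees=degs,
        absent=absent,
    )


@dataclass(frozen=True)
class HubConnectivity:
    table: dict[str, frozenset[str]]  # gene -> hubs it touches
    n_any: int
    n_all: int


def hub_connectivity(
    interactome: Interactome, genes: Iterable[str], hubs: Sequence[str]
) -> HubConnectivity:
    """Which genes touch which of a small list of hub regulators.

    Genes absent from the interactome count as connected to none.
    """
    if not hubs:
        raise DataError("hub list is empty")
    genes = set(genes)
    if not genes:
        raise DataError("gene set is empty")
    hubset = list(dict.fromkeys(hubs))
    table: dict[str, frozenset[str]] = {}
    for g in sorted(genes):
        if g in interactome.nodes:
            touched = frozenset(h for h in hubset if interactome.has_edge(g, h))
        else:
            touched = frozenset()
        table[g] = touched
    n_any = sum(1 for t in table.values() if t)
    n_all = sum(1 for t in table.values() if len(t) == len(hubset))
    return HubConnectivity(table=table, n_any=n_any, n_all=n_all)
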