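"""Readers and writers for the external formats the pipeline touches.

Edge lists are BioGRID-style two-column (plus metadata) TSV/CSV files; gene
sets are one-gene-per-row tables; orthology tables are three-column
(species-A gene, species-B gene, cluster id).  All loaders validate their
input, canonicalize identifiers through an optional alias map, and never
silently drop rows: every row is either returned, counted in a logged drop
tally, or raises.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .orthology import OrthologyMap

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {
    "gene", "gene_a", "gene_b", "genea", "geneb", "source", "target",
    "interactor_a", "interactor_b", "official_symbol_a", "official_symbol_b",
    "id", "symbol", "name", "species_a", "species_b", "cluster", "cluster_id",
}


class DataError(ValueError):
    """Malformed or empty input data."""


@dataclass(frozen=True)
class EdgeRecord:
    """One physical-interaction row: two gene identifiers plus metadata."""

    gene_a: str
    gene_b: str
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_a or not self.gene_b:
            raise DataError("edge record endpoints must be non-empty")


class GeneAliasMap:
    """A function alias -> canonical gene id.

    Canonical ids map to themselves, so applying the map twice equals
    applying it once.  Unknown aliases pass through unchanged unless
    ``strict`` is requested at the call site.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        for alias, canon in (mapping or {}).items():
            self.add(alias, canon)

    def add(self, alias: str, canonical: str) -> None:
        alias, canonical = alias.strip(), canonical.strip()
        if not alias or not canonical:
            raise DataError("empty alias or canonical id")
        prior = self._map.get(alias)
        if prior is not None and prior != canonical:
            raise DataError(f"alias {alias!r} maps to both {prior!r} and {canonical!r}")
        self._map[alias] = canonical
        self._map.setdefault(canonical, canonical)

    def canonical(self, gene: str, strict: bool = False) -> str:
        gene = gene.strip()
        try:
            return self._map[gene]
        except KeyError:
            if strict:
                raise DataError(f"unknown alias: {gene!r}") from None
            return gene

    def __contains__(self, gene: str) -> bool:
        return gene in self._map

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_table(cls, path: str | Path, delimiter: str | None = None) -> "GeneAliasMap":
        rows = _read_rows(path, delimiter)
        amap = cls()
        for lineno, row in rows:
            if len(row) < 2:
                raise DataError(f"{path}: line {lineno}: alias table needs 2 columns")
            amap.add(row[0], row[1])
        return amap


@dataclass(frozen=True)
class AnnotatedGeneSet:
    """A labelled set of canonical gene ids for one species."""

    species: str
    genes: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.species:
            raise DataError("species label must be non-empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


# ---------------------------------------------------------------------------
# row-level helpers

def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def _read_rows(path: str | Path, delimiter: str | None) -> list[tuple[int, list[str]]]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    text = path.read_text()
    lines = [ln for ln in text.splitlines()]
    content = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.lstrip().startswith("#")]
    if not content:
        raise DataError(f"{path}: file is empty")
    delim = delimiter or _sniff_delimiter(content[0][1])
    reader_rows = []
    for lineno, ln in content:
        row = next(csv.reader([ln], delimiter=delim))
        reader_rows.append((lineno, [cell.strip() for cell in row]))
    return reader_rows


def _looks_like_header(row: list[str]) -> bool:
    return any(cell.lower() in _HEADER_TOKENS for cell in row)


def _split_header(
    rows: list[tuple[int, list[str]]], header: bool | None
) -> tuple[list[str] | None, list[tuple[int, list[str]]]]:
    if header is None:
        header = _looks_like_header(rows[0][1])
    if header:
        return rows[0][1], rows[1:]
    return None, rows


# ---------------------------------------------------------------------------
# loaders

def load_edge_list(
    path: str | Path,
    alias_map: GeneAliasMap | None = None,
    metadata_filter: Mapping[str, Iterable[str]] | None = None,
    delimiter: str | None = None,
    header: bool | None = None,
) -> list[EdgeRecord]:
    """Parse a PPI edge list into :class:`EdgeRecord` rows.

    Duplicate and reversed rows are preserved here; collapsing them is the
    graph layer's job.  Rows failing ``metadata_filter`` (a mapping from
    metadata column name to allowed values) are dropped with a logged count.
    """
    rows = _read_rows(path, delimiter)
    colnames, body = _split_header(rows, header)
    if not body:
        raise DataError(f"{path}: no edges")
    allowed = {k: set(v) for k, v in (metadata_filter or {}).items()}
    records: list[EdgeRecord] = []
    dropped = 0
    for lineno, row in body:
        if len(row) < 2 or not row[0] or not row[1]:
            raise DataError(f"{path}: line {lineno}: expected >=2 gene columns")
        meta_cells = row[2:]
        if colnames is not None:
            keys = colnames[2 : 2 + len(meta_cells)]
        else:
            keys = [f"col{i + 3}" for i in range(len(meta_cells))]
        meta = dict(zip(keys, meta_cells))
        if allowed and any(meta.get(k) not in v for k, v in allowed.items()):
            dropped += 1
            continue
        a, b = row[0], row[1]
        if alias_map is not None:
            a, b = alias_map.canonical(a), alias_map.canonical(b)
        records.append(EdgeRecord(a, b, meta))
    if dropped:
        logger.info("load_edge_list(%s): dropped %d rows by metadata filter", path, dropped)
    if not records:
        raise DataError(f"{path}: no edges after filtering")
    return records


def load_gene_set(
    path: str | Path,
    species: str,
    label: str = "",
    alias_map: GeneAliasMap | None = None,
    strict: bool = False,
    delimiter: str | None = None,
    header: bool | None = None,
) -> AnnotatedGeneSet:
    """Read a one-gene-per-row table (first column used) into a gene set."""
    rows = _read_rows(path, delimiter)
    _, body = _split_header(rows, header)
    if not body:
        raise DataError(f"{path}: gene set file has no rows")
    genes: set[str] = set()
    unknown: list[str] = []
    for lineno, row in body:
        gene = row[0]
        if not gene:
            raise DataError(f"{path}: line {lineno}: empty gene id")
        if alias_map is not None:
            if strict and gene not in alias_map:
                unknown.append(gene)
                continue
            gene = alias_map.canonical(gene)
        genes.add(gene)
    if unknown:
        raise DataError(f"{path}: unknown aliases in strict mode: {sorted(unknown)}")
    return AnnotatedGeneSet(species=species, genes=frozenset(genes), label=label)


def load_orthology_table(
    path: str | Path,
    species_pair: tuple[str, str] = ("speciesA", "speciesB"),
    delimiter: str | None = None,
    header: bool | None = None,
) -> OrthologyMap:
    """Read (species-A gene, species-B gene[, cluster id]) rows.

    Many-to-many pairs are preserved; exact duplicate pairs collapse.
    """
    rows = _read_rows(path, delimiter)
    _, body = _split_header(rows, header)
    if not body:
        raise DataError(f"{path}: orthology table has no rows")
    pairs: set[tuple[str, str]] = set()
    clusters: dict[tuple[str, str], str] = {}
    for lineno, row in body:
        if len(row) < 2 or not row[0] or not row[1]:
            raise DataError(f"{path}: line {lineno}: expected 2 gene columns")
        pair = (row[0], row[1])
        pairs.add(pair)
        if len(row) > 2 and row[2]:
            clusters[pair] = row[2]
    return OrthologyMap(species_pair=species_pair, pairs=frozenset(pairs), clusters=clusters)


# ---------------------------------------------------------------------------
# network export / import

_EXPORT_FORMATS = ("graphml", "tsv")


def export_network(network, path: str | Path, format: str = "graphml") -> None:
    """Write a longevity network with its core/partner node roles.

    GraphML round-trips node roles as attributes; the TSV variant writes one
    edge per row and a sibling ``<path>.nodes.tsv`` role table.
    """
    fmt = format.lower()
    if fmt not in _EXPORT_FORMATS:
        raise DataError(f"unknown format {format!r}; supported: {', '.join(_EXPORT_FORMATS)}")
    g = network.to_graph()
    if g.number_of_nodes() == 0:
        raise DataError("refusing to export an empty network")
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        with path.open("w") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
                fh.write(f"{a}\t{b}\n")
        nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
        with nodes_path.open("w") as fh:
            for n in sorted(g.nodes()):
                fh.write(f"{n}\t{g.nodes[n]['role']}\n")


def load_survival_csv(path: str | Path) -> dict:
    """Read per-animal survival rows (gene,group,time,event) into datasets.

    Returns a mapping gene -> SurvivalDataset; control animals (group
    'control') appear under the key 'control'.
    """
    import pandas as pd

    from .screen import SurvivalDataset

    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    df = pd.read_csv(path)
    required = {"gene", "group", "time", "event"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: survival CSV needs columns {sorted(required)}")
    if df.empty:
        raise DataError(f"{path}: survival CSV has no rows")
    out: dict[str, SurvivalDataset] = {}
    for gene, sub in df.groupby("gene", sort=True):
        key = "control" if (sub["group"] == "control").all() else str(gene)
        out[key] = SurvivalDataset(
            label=key,
            times=tuple(float(t) for t in sub["time"]),
            events=tuple(bool(int(e)) for e in sub["event"]),
        )
    return out


def load_thrashing_csv(path: str | Path) -> dict:
    """Read thrashing counts (gene,day,treated_alive,treated_total,
    control_alive,control_total) into per-gene ThrashingRecords."""
    import pandas as pd

    from .screen import ThrashingRecord

    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    df = pd.read_csv(path)
    required = {
        "gene", "day", "treated_alive", "treated_total",
        "control_alive", "control_total",
    }
    if not required.issubset(df.columns):
        raise DataError(f"{path}: thrashing CSV needs columns {sorted(required)}")
    records: dict[str, ThrashingRecord] = {}
    for gene, sub in df.groupby("gene", sort=True):
        sub = sub.sort_values("day")
        if len(sub) != 4:
            raise DataError(f"{path}: gene {gene}: expected 4 time points, got {len(sub)}")
        records[str(gene)] = ThrashingRecord(
            gene=str(gene),
            survival_fraction=tuple(
                a / t if t else 0.0
                for a, t in zip(sub["treated_alive"], sub["treated_total"])
            ),
            control_fraction=tuple(
                a / t if t else 0.0
                for a, t in zip(sub["control_alive"], sub["control_total"])
            ),
            n_scored=int(sub["treated_total"].iloc[0]),
        )
    return records


def import_network(path: str | Path):
    """Re-load a GraphML export as a :class:`~longnet.network.LongevityNetwork`."""
    from .network import LongevityNetwork

    g = nx.read_graphml(Path(path))
    core = frozenset(n for n, d in g.nodes(data=True) if d.get("role") == "core")
    partners = frozenset(n for n, d in g.nodes(data=True) if d.get("role") == "partner")
    edges = frozenset(frozenset(e) for e in g.edges())
    return LongevityNetwork(core_nodes=core, partner_nodes=partners, edges=edges, parent=None)
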