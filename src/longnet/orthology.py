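"""Cross-species gene-set transfer through many-to-many orthology maps.

An :class:`OrthologyMap` is a set of (species-A gene, species-B gene)
correspondences, InParanoid-cluster style: one gene may map to several
genes on the other side (in-paralogs) and vice versa.  Transfer of a gene
set is the union of all orthologs of its members ("non-redundant": plain
set union on canonical ids, no best-hit collapsing), with unmapped genes
dropped from the result but always enumerated in the mapping report so
transfer losses stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence


@dataclass(frozen=True)
class OrthologyMap:
    """Many-to-many gene correspondence between two species."""

    species_pair: tuple[str, str]
    pairs: frozenset[tuple[str, str]]
    clusters: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def forward(self) -> dict[str, set[str]]:
        """species A gene -> set of species B orthologs."""
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, set()).add(b)
        return out

    def reverse(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(b, set()).add(a)
        return out

    def transpose(self) -> "OrthologyMap":
        return OrthologyMap(
            species_pair=(self.species_pair[1], self.species_pair[0]),
            pairs=frozenset((b, a) for a, b in self.pairs),
            clusters={(b, a): c for (a, b), c in self.clusters.items()},
        )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class MappingReport:
    """Per-gene accounting of one transfer: |input| = |mapped| + |unmapped|."""

    mapped: Mapping[str, frozenset[str]]
    unmapped: frozenset[str]
    expansions: Mapping[str, frozenset[str]]  # genes with >1 ortholog

    @property
    def n_input(self) -> int:
        return len(self.mapped) + len(self.unmapped)


def map_gene_set(genes, omap: OrthologyMap, direction: str = "ab"):
    """Map an annotated gene set across species.

    direction "ab" maps species_pair[0] -> species_pair[1]; "ba" the reverse.
    Returns (mapped AnnotatedGeneSet, MappingReport).
    """
    from .io import AnnotatedGeneSet, DataError

    if direction not in ("ab", "ba"):
        raise DataError(f"direction must be 'ab' or 'ba', got {direction!r}")
    src, dst = omap.species_pair if direction == "ab" else omap.species_pair[::-1]
    if genes.species != src:
        raise DataError(
            f"gene set species {genes.species!r} does not match map source {src!r}"
        )
    lookup = omap.forward() if direction == "ab" else omap.reverse()
    mapped: dict[str, frozenset[str]] = {}
    unmapped: set[str] = set()
    for g in genes.genes:
        targets = lookup.get(g)
        if targets:
            mapped[g] = frozenset(targets)
        else:
            unmapped.add(g)
    out_genes = frozenset().union(*mapped.values()) if mapped else frozenset()
    report = MappingReport(
        mapped=mapped,
        unmapped=frozenset(unmapped),
        expansions={g: t for g, t in mapped.items() if len(t) > 1},
    )
    out = AnnotatedGeneSet(species=dst, genes=out_genes, label=genes.label)
    return out, report


def build_cross_species_core(
    native_lags,
    foreign_lag_sets: Sequence,
    maps: Sequence[OrthologyMap],
):
    """Union the native longevity-gene list with mapped foreign lists.

    Each foreign set must come with an orthology map whose target side is
    the native species.  Returns (core AnnotatedGeneSet, provenance) where
    provenance maps each core gene to the sorted list of species that
    contributed it ("native" and/or foreign species labels).
    """
    from .io import AnnotatedGeneSet, DataError

    if len(foreign_lag_sets) != len(maps):
        raise DataError("each foreign LAG set needs a matching orthology map")
    native_species = native_lags.species
    provenance: dict[str, set[str]] = {g: {"native"} for g in native_lags.genes}
    for fset, omap in zip(foreign_lag_sets, maps):
        if omap.species_pair[0] == fset.species and omap.species_pair[1] == native_species:
            direction = "ab"
        elif omap.species_pair[1] == fset.species and omap.species_pair[0] == native_species:
            direction = "ba"
        else:
            raise DataError(
                f"no orthology map from {fset.species!r} to {native_species!r}"
            )
        mapped, _ = map_gene_set(fset, omap, direction)
        for g in mapped.genes:
            provenance.setdefault(g, set()).add(fset.species)
    core = AnnotatedGeneSet(
        species=native_species,
        genes=frozenset(provenance),
        label="cross-species core",
    )
    return core, {g: sorted(v) for g, v in provenance.items()}
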