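"""Candidate-gene selection.

A gene qualifies as a candidate longevity regulator when it (1) is a
first-order partner in the native longevity network or the native ortholog
of a partner from the foreign-species network, (2) has not previously been
reported as a longevity-associated gene in any supplied species, and (3) is
essential for development and growth.  Candidates carry a provenance class
(native-network only / foreign-network only / shared) and a per-gene filter
trail recording why excluded genes fell out, so the selection funnel is
auditable: every pool gene appears exactly once in the candidate set or the
trail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .io import AnnotatedGeneSet, DataError
from .network import LongevityNetwork

WLN_ONLY = "WLN_only"
HLN_ONLY = "HLN_only"
SHARED = "shared"

DEFAULT_ESSENTIAL_TERMS = frozenset(
    {"embryonic lethal", "larval lethal", "larval arrest", "sterile"}
)


@dataclass(frozen=True)
class CandidateSet:
    candidates: frozenset[str]
    provenance: Mapping[str, str]
    filter_trail: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if set(self.provenance) != set(self.candidates):
            raise DataError("provenance must cover exactly the candidate set")

    @property
    def counts(self) -> dict[str, int]:
        c = {WLN_ONLY: 0, HLN_ONLY: 0, SHARED: 0}
        for v in self.provenance.values():
            c[v] += 1
        c["total"] = len(self.candidates)
        return c


def _provenance_class(gene: str, wln_pool: frozenset[str], hln_pool: frozenset[str]) -> str:
    in_w, in_h = gene in wln_pool, gene in hln_pool
    if in_w and in_h:
        return SHARED
    return WLN_ONLY if in_w else HLN_ONLY


def select_candidates(
    wln: LongevityNetwork,
    hln_partner_orthologs: AnnotatedGeneSet,
    known_lags_all_species: AnnotatedGeneSet,
    essential: AnnotatedGeneSet,
) -> CandidateSet:
    """Apply the three selection criteria; all inputs in the native namespace."""
    wln_pool = wln.partner_nodes
    hln_pool = frozenset(hln_partner_orthologs.genes)
    pool = wln_pool | hln_pool
    if not pool:
        raise DataError("candidate pool is empty")
    candidates: dict[str, str] = {}
    trail: dict[str, tuple[str, ...]] = {}
    for gene in sorted(pool):
        reasons = []
        if gene in known_lags_all_species.genes:
            reasons.append("known_lag")
        if gene not in essential.genes:
            reasons.append("not_essential")
        if reasons:
            trail[gene] = tuple(reasons)
        else:
            candidates[gene] = _provenance_class(gene, wln_pool, hln_pool)
    return CandidateSet(
        candidates=frozenset(candidates),
        provenance=candidates,
        filter_trail=trail,
    )


def apply_clone_availability(candidates: CandidateSet, clones: AnnotatedGeneSet) -> CandidateSet:
    """Intersect with the RNAi-clone-available set, preserving provenance."""
    kept = {g: p for g, p in candidates.provenance.items() if g in clones.genes}
    trail = dict(candidates.filter_trail)
    for g in candidates.candidates - set(kept):
        trail[g] = trail.get(g, ()) + ("no_clone",)
    return CandidateSet(
        candidates=frozenset(kept), provenance=kept, filter_trail=trail
    )


def partition_counts(candidates: CandidateSet) -> tuple[int, int, int, int]:
    """(WLN_only, HLN_only, shared, total); total is always their sum."""
    c = candidates.counts
    return c[WLN_ONLY], c[HLN_ONLY], c[SHARED], c["total"]


def essential_from_phenotypes(
    phenotypes: Mapping[str, str],
    species: str,
    qualifying_terms: frozenset[str] = DEFAULT_ESSENTIAL_TERMS,
) -> AnnotatedGeneSet:
    """Derive an essential-gene set from a gene -> phenotype-term mapping."""
    genes = frozenset(
        g for g, term in phenotypes.items() if term.strip().lower() in qualifying_terms
    )
    return AnnotatedGeneSet(species=species, genes=genes, label="essential")
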