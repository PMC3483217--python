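"""Orchestration of the two workflows: candidate prediction and screen analysis.

`run_predict` goes from raw files (edge list, core gene set, orthology
table, foreign-network partner set, essentiality/known-gene/clone lists)
to a candidate table plus a machine-readable JSON report.  `run_screen`
takes thrashing records and survival datasets through primary
classification and longitudinal log-rank confirmation; `run_screen_stats`
is its file-based wrapper.  Reports are written deterministically (sorted
keys, no timestamps) and carry a provenance block (config hash, seed) so a
run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import io as lio
from .io import AnnotatedGeneSet, DataError
from .netstats import interconnectivity, permutation_null
from .network import build_interactome, build_longevity_network, coverage_fraction
from .orthology import map_gene_set
from .screen import (
    LONG, NONE, SHORT,
    EffectMeasure, ScreenSummary, SurvivalDataset, ThrashingRecord,
    classify_thrashing, extrapolate_verified, fold_improvement, km_estimate,
    logrank_test, percent_changes, primary_detection_rates, round_half_up,
    verification_frequency,
)
from .selection import apply_clone_availability, partition_counts, select_candidates

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Input paths and the screen's fixed thresholds."""

    edges: str = "edges.tsv"
    core: str = "core.tsv"
    orthology: str = "orthology.tsv"
    hln_partners: str = "hln_partners.tsv"
    essential: str = "essential.tsv"
    known_lags: str = "known_lags.tsv"
    clones: str = "clones.tsv"
    survival: str = "survival.csv"
    thrashing: str = "thrashing.csv"
    out_dir: str = "results"
    species: str = "worm"
    foreign_species: str = "human"
    n_permutations: int = 999
    seed: int = 0
    sampling_mode: str = "uniform"
    threshold: float = 0.10          # thrashing relative-change threshold
    min_timepoints: int = 3
    alpha: float = 0.05              # log-rank significance
    modest_cutoff: float = 10.0
    baseline_freqs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise DataError("threshold must lie in (0, 1)")
        if not (1 <= self.min_timepoints <= 4):
            raise DataError("min_timepoints must lie in 1..4")
        if not (0 < self.alpha < 1):
            raise DataError("alpha must lie in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["baseline_freqs"] = list(d["baseline_freqs"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "baseline_freqs" in d:
            d["baseline_freqs"] = tuple(d["baseline_freqs"])
        return cls(**d)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["baseline_freqs"] = list(d["baseline_freqs"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "config_sha256": config.digest(),
        "seed": config.seed,
    }


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# prediction workflow

def run_predict(config: PipelineConfig) -> dict:
    """Build networks, test interconnectivity, select candidates; write files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = lio.load_edge_list(config.edges)
    interactome = build_interactome(records, species=config.species)
    core = lio.load_gene_set(config.core, species=config.species, label="core LAGs")
    wln = build_longevity_network(interactome, core)
    cov = coverage_fraction(wln, core, interactome)
    inter = interconnectivity(interactome, core.genes)
    null = permutation_null(
        interactome, core.genes, config.n_permutations, config.seed,
        config.sampling_mode,
    )
    omap = lio.load_orthology_table(
        config.orthology, species_pair=(config.species, config.foreign_species)
    )
    foreign = lio.load_gene_set(
        config.hln_partners, species=config.foreign_species, label="foreign partners"
    )
    hln_orthologs, map_report = map_gene_set(foreign, omap, direction="ba")
    essential = lio.load_gene_set(config.essential, species=config.species)
    known = lio.load_gene_set(config.known_lags, species=config.species)
    clones = lio.load_gene_set(config.clones, species=config.species)
    selected = select_candidates(wln, hln_orthologs, known, essential)
    candidates = apply_clone_availability(selected, clones)
    wln_only, hln_only, shared, total = partition_counts(candidates)

    lio.export_network(wln, out / "wln.graphml", "graphml")
    with (out / "candidates.tsv").open("w") as fh:
        fh.write("gene\tprovenance\n")
        for g in sorted(candidates.candidates):
            fh.write(f"{g}\t{candidates.provenance[g]}\n")
    report = {
        "provenance": _provenance(config),
        "interactome": {"nodes": interactome.n_nodes, "edges": interactome.n_edges},
        "network": wln.report(),
        "coverage_fraction": cov,
        "coverage_pct": round_half_up(100 * cov, 1),
        "interconnectivity": {
            "set_size": inter.set_size,
            "n_present": inter.n_present,
            "n_interconnected": inter.n_interconnected,
            "fraction": inter.fraction,
            "p_value": null.p_value,
            "n_permutations": null.n_permutations,
            "null_mean": sum(null.null_fractions) / len(null.null_fractions),
            "sampling_mode": null.sampling_mode,
        },
        "ortholog_transfer": {
            "n_foreign": len(foreign),
            "n_mapped": len(map_report.mapped),
            "n_unmapped": len(map_report.unmapped),
        },
        "selection_funnel": {
            "pool": len(candidates.candidates) + len(candidates.filter_trail),
            "after_filters": len(selected.candidates),
            "after_clones": total,
        },
        "partition": {
            "WLN_only": wln_only, "HLN_only": hln_only,
            "shared": shared, "total": total,
        },
    }
    _write_json(report, out / "predict_report.json")
    return report


# ---------------------------------------------------------------------------
# screen workflow

@dataclass(frozen=True)
class ScreenResult:
    calls: Mapping[str, str]                       # primary phenotype per gene
    verified_long: frozenset[str]
    verified_short: frozenset[str]
    effects: tuple[EffectMeasure, ...]             # verified genes only
    summaries: Mapping[str, ScreenSummary]         # per class + "total"
    logrank_p: Mapping[str, float]


def run_screen(
    thrashing: Mapping[str, ThrashingRecord],
    lifespans: Mapping[str, SurvivalDataset],
    provenance: Mapping[str, str] | None = None,
    threshold: float = 0.10,
    min_timepoints: int = 3,
    alpha: float = 0.05,
    retest: frozenset[str] | None = None,
) -> ScreenResult:
    """Primary classification then longitudinal confirmation.

    Every preliminary hit with survival data is retested (pass ``retest``
    to restrict, emulating a capacity-limited longitudinal stage); a gene
    is verified when the log-rank p-value is below alpha and the sign of
    the mean-lifespan change agrees with the primary call.
    """
    if "control" not in lifespans:
        raise DataError("survival data must include a 'control' group")
    control = lifespans["control"]
    calls = {
        g: classify_thrashing(rec, threshold, min_timepoints)
        for g, rec in sorted(thrashing.items())
        if g != "control"
    }
    prelim = {d: [g for g, c in calls.items() if c == d] for d in (LONG, SHORT)}
    verified: dict[str, set[str]] = {LONG: set(), SHORT: set()}
    retested: dict[str, set[str]] = {LONG: set(), SHORT: set()}
    effects: list[EffectMeasure] = []
    pvals: dict[str, float] = {}
    for direction in (LONG, SHORT):
        for g in prelim[direction]:
            if g not in lifespans:
                continue
            if retest is not None and g not in retest:
                continue
            retested[direction].add(g)
            _, p = logrank_test(lifespans[g], control)
            pvals[g] = p
            eff = percent_changes(lifespans[g], control, gene=g)
            agrees = eff.pct_delta_mean > 0 if direction == LONG else eff.pct_delta_mean < 0
            if p < alpha and agrees:
                verified[direction].add(g)
                effects.append(eff)

    def _summary(genes: set[str] | None) -> ScreenSummary:
        sel = (lambda gs: gs if genes is None else [g for g in gs if g in genes])
        screened = len(calls) if genes is None else len(genes)
        return ScreenSummary(
            genes_screened=screened,
            preliminary_long=len(sel(prelim[LONG])),
            preliminary_short=len(sel(prelim[SHORT])),
            retested_long=len(sel(retested[LONG])),
            retested_short=len(sel(retested[SHORT])),
            verified_long=len(sel(verified[LONG])),
            verified_short=len(sel(verified[SHORT])),
        )

    summaries = {"total": _summary(None)}
    if provenance:
        for cls_name in sorted(set(provenance.values())):
            members = {g for g, c in provenance.items() if c == cls_name}
            summaries[cls_name] = _summary(members)
    return ScreenResult(
        calls=calls,
        verified_long=frozenset(verified[LONG]),
        verified_short=frozenset(verified[SHORT]),
        effects=tuple(sorted(effects, key=lambda e: -e.pct_delta_mean)),
        summaries=summaries,
        logrank_p=pvals,
    )


def screen_report(
    result: ScreenResult,
    modest_cutoff: float = 10.0,
    baseline_freqs: Sequence[float] = (),
) -> dict:
    """Tables-style summary JSON for a screen result."""
    total = result.summaries["total"]
    report: dict = {
        "funnel": {
            name: dataclasses.asdict(s) for name, s in sorted(result.summaries.items())
        },
        "verification_frequency": {
            "long_pct": verification_frequency(total, LONG),
            "short_pct": verification_frequency(total, SHORT),
        },
        "detection_rates": {
            name: dict(zip(
                ("any_pct", "long_pct", "short_pct"),
                primary_detection_rates(
                    s.genes_screened, s.preliminary_long, s.preliminary_short
                ),
            ))
            for name, s in sorted(result.summaries.items())
            if s.genes_screened
        },
    }
    if total.retested_long:
        count, pct = extrapolate_verified(
            total.preliminary_long, total.retested_long, total.verified_long,
            total.genes_screened,
        )
        report["extrapolated_long"] = {"count": count, "pct": pct}
    if total.retested_short:
        count, pct = extrapolate_verified(
            total.preliminary_short, total.retested_short, total.verified_short,
            total.genes_screened,
        )
        report["extrapolated_short"] = {"count": count, "pct": pct}
    if baseline_freqs:
        raw = 100.0 * total.verified_long / total.genes_screened
        fold_int, fold_raw = fold_improvement(raw, baseline_freqs)
        report["fold_improvement"] = {"rounded": fold_int, "raw": fold_raw}
    longs = [e for e in result.effects if e.pct_delta_mean > 0]
    if longs:
        from .screen import summarize_effects

        n, mean, n_modest = summarize_effects(longs, LONG, modest_cutoff)
        report["long_effect_summary"] = {
            "n": n, "mean_pct": mean, "n_modest": n_modest,
        }
    return report


def run_screen_stats(config: PipelineConfig) -> dict:
    """File-based screen workflow: classify, confirm, write tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thrashing = lio.load_thrashing_csv(config.thrashing)
    lifespans = lio.load_survival_csv(config.survival)
    provenance: dict[str, str] | None = None
    cand_path = out / "candidates.tsv"
    if cand_path.exists():
        provenance = {}
        for line in cand_path.read_text().splitlines()[1:]:
            gene, cls_name = line.split("\t")
            provenance[gene] = cls_name
    result = run_screen(
        thrashing, lifespans, provenance,
        threshold=config.threshold, min_timepoints=config.min_timepoints,
        alpha=config.alpha,
    )
    with (out / "effects.tsv").open("w") as fh:
        fh.write("gene\tpct_delta_mean\tpct_delta_max\tlogrank_p\n")
        for e in result.effects:
            fh.write(
                f"{e.gene}\t{e.pct_delta_mean:.4f}\t{e.pct_delta_max:.4f}"
                f"\t{result.logrank_p[e.gene]:.6g}\n"
            )
    report = screen_report(result, config.modest_cutoff, config.baseline_freqs)
    report["provenance"] = _provenance(config)
    _write_json(report, out / "screen_report.json")
    return report
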