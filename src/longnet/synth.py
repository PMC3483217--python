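"""Synthetic study worlds with known ground truth.

Generates every input the pipeline consumes: a scale-free interactome with
a planted longevity-gene module of elevated interconnectivity, boolean
essentiality labels enriched in the module, a many-to-many orthology map to
a mirrored second species, Gompertz lifespan samples with per-gene
multiplicative effects, and binomially sampled thrashing survival
fractions.  Every generator is a pure function of (parameters, seed); a
single master seed spawns fixed per-component child seeds, so regenerating
one component never perturbs the others.

Default mortality model: Gompertz hazard h(t) = a * exp(b t) with rate of
aging b = 0.30/day and baseline hazard a = 7.734e-4/day, giving a control
mean lifespan of 18 days — an eri-1(mg366)-like assay at 20 degrees C whose
mortality phase spans the day-15..21 scoring window.  A gene's lifespan
factor f rescales time (T = f * T_baseline), so f = 1.25 shifts the mean
lifespan by +25%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .io import AnnotatedGeneSet, DataError
from .network import Interactome, LongevityNetwork, build_longevity_network
from .orthology import OrthologyMap, map_gene_set
from .screen import SurvivalDataset, ThrashingRecord
from .selection import CandidateSet, apply_clone_availability, select_candidates

GOMPERTZ_SHAPE = 0.30        # rate of aging b, 1/day
GOMPERTZ_SCALE = 7.734e-4    # baseline hazard a, 1/day; control mean ~18 d
THRASHING_DAYS = (15.0, 17.0, 19.0, 21.0)


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _gene_name(i: int) -> str:
    return f"g{i:04d}"


# ---------------------------------------------------------------------------
# interactome

def gen_interactome(
    n_nodes: int,
    model: str = "scale_free",
    seed: int = 0,
    species: str = "worm",
    **model_params,
) -> Interactome:
    """Random PPI graph: scale_free (preferential attachment), erdos_renyi,
    or configuration (power-law degree sequence)."""
    if n_nodes < 10:
        raise DataError("need at least 10 nodes for a meaningful interactome")
    if model == "scale_free":
        m = int(model_params.get("m", 3))
        g = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    elif model == "erdos_renyi":
        p = float(model_params.get("p", 0.02))
        g = nx.gnp_random_graph(n_nodes, p, seed=seed)
    elif model == "configuration":
        gamma = float(model_params.get("gamma", 2.5))
        rng = np.random.default_rng(seed)
        deg = np.clip(np.round(rng.pareto(gamma - 1, n_nodes) + 1), 1, n_nodes - 1).astype(int)
        if deg.sum() % 2:
            deg[0] += 1
        g = nx.Graph(nx.configuration_model(deg, seed=seed))
        g.remove_edges_from(nx.selfloop_edges(g))
    else:
        raise DataError(f"unknown interactome model {model!r}")
    if g.number_of_edges() == 0:
        raise DataError("model parameters produced an empty graph")
    g = nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes()})
    return Interactome(graph=g, species=species)


def plant_core_module(
    interactome: Interactome,
    k: int,
    density_boost: float = 4.0,
    seed: int = 0,
) -> tuple[Interactome, frozenset[str]]:
    """Select k nodes and densify their internal edges to density_boost times
    the background pair density.  A boost of 1 leaves the graph untouched."""
    n = interactome.n_nodes
    if k >= n:
        raise DataError("module size must be smaller than the graph")
    if density_boost < 1:
        raise DataError("density_boost must be >= 1")
    background = 2 * interactome.n_edges / (n * (n - 1))
    target_density = density_boost * background
    if target_density > 1:
        raise DataError("requested internal density exceeds 1")
    rng = np.random.default_rng(seed)
    nodes = sorted(interactome.nodes)
    core = sorted(rng.choice(np.array(nodes), size=k, replace=False).tolist())
    if density_boost == 1:
        return interactome, frozenset(core)
    g = interactome.graph.copy()
    target_edges = int(round(target_density * k * (k - 1) / 2))
    missing = [
        (core[i], core[j])
        for i in range(k)
        for j in range(i + 1, k)
        if not g.has_edge(core[i], core[j])
    ]
    have = k * (k - 1) // 2 - len(missing)
    n_add = max(0, target_edges - have)
    if n_add > 0:
        idx = rng.choice(len(missing), size=min(n_add, len(missing)), replace=False)
        for i in sorted(idx.tolist()):
            g.add_edge(*missing[i])
    return Interactome(graph=g, species=interactome.species), frozenset(core)


# ---------------------------------------------------------------------------
# annotations and orthology

def gen_annotations(
    interactome: Interactome,
    essential_fraction: float,
    core_essential_enrichment: float = 1.0,
    seed: int = 0,
    core: frozenset[str] = frozenset(),
) -> dict[str, bool]:
    """Boolean essentiality labels; module genes enriched by the given factor."""
    if not (0 <= essential_fraction <= 1):
        raise DataError("essential_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p_core = min(1.0, essential_fraction * core_essential_enrichment)
    labels = {}
    for gene in sorted(interactome.nodes):
        p = p_core if gene in core else essential_fraction
        labels[gene] = bool(rng.random() < p)
    return labels


def gen_orthology(
    genes: Sequence[str],
    coverage: float = 0.8,
    paralog_rate: float = 0.1,
    seed: int = 0,
    species_pair: tuple[str, str] = ("worm", "human"),
) -> OrthologyMap:
    """Mirror each gene into the second species with the given coverage;
    mapped genes gain an extra paralog with probability paralog_rate."""
    if not (0 <= coverage <= 1 and 0 <= paralog_rate <= 1):
        raise DataError("coverage and paralog_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = set()
    for g in sorted(genes):
        if rng.random() < coverage:
            pairs.add((g, f"h_{g}"))
            if rng.random() < paralog_rate:
                pairs.add((g, f"h_{g}_p"))
    return OrthologyMap(species_pair=species_pair, pairs=frozenset(pairs))


# ---------------------------------------------------------------------------
# lifespans and thrashing

def gompertz_survival(t, shape: float = GOMPERTZ_SHAPE, scale: float = GOMPERTZ_SCALE):
    """S(t) for hazard scale * exp(shape * t)."""
    return np.exp(-(scale / shape) * np.expm1(shape * np.asarray(t, dtype=float)))


def sample_gompertz(
    n: int, shape: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    u = rng.random(n)
    return (1.0 / shape) * np.log1p(-shape * np.log(u) / scale)


def gen_lifespans(
    gene_effects: Mapping[str, float],
    n_animals: int = 90,
    gompertz_shape: float = GOMPERTZ_SHAPE,
    gompertz_scale: float = GOMPERTZ_SCALE,
    censor_rate: float = 0.1,
    seed: int = 0,
) -> dict[str, SurvivalDataset]:
    """Per-gene survival data plus a 'control' group (factor 1.0).

    Each animal's death time is factor * Gompertz(shape, scale); a fraction
    censor_rate of animals is right-censored at a uniform time before death
    (bagging / wall deaths in a real assay).
    """
    if n_animals < 10:
        raise DataError("need at least 10 animals per group")
    if gompertz_shape <= 0 or gompertz_scale <= 0:
        raise DataError("Gompertz shape and scale must be positive")
    if not (0 <= censor_rate <= 1):
        raise DataError("censor_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: dict[str, SurvivalDataset] = {}
    for gene in ["control"] + sorted(g for g in gene_effects if g != "control"):
        factor = 1.0 if gene == "control" else float(gene_effects[gene])
        if factor <= 0:
            raise DataError(f"{gene}: lifespan factor must be positive")
        deaths = factor * sample_gompertz(n_animals, gompertz_shape, gompertz_scale, rng)
        censored = rng.random(n_animals) < censor_rate
        times = np.where(censored, deaths * rng.uniform(0.3, 1.0, n_animals), deaths)
        out[gene] = SurvivalDataset(
            label=gene,
            times=tuple(float(t) for t in times),
            events=tuple(bool(not c) for c in censored),
        )
    return out


def gen_thrashing(
    gene_effects: Mapping[str, float],
    days: Sequence[float] = THRASHING_DAYS,
    n_scored: int = 30,
    seed: int = 0,
    gompertz_shape: float = GOMPERTZ_SHAPE,
    gompertz_scale: float = GOMPERTZ_SCALE,
) -> dict[str, ThrashingRecord]:
    """One thrashing record per gene: on each scoring day the surviving
    fraction is a binomial draw at the group's true survival probability,
    with a matched control draw per record."""
    rng = np.random.default_rng(seed)
    days = np.asarray(days, dtype=float)
    records: dict[str, ThrashingRecord] = {}
    control_p = gompertz_survival(days, gompertz_shape, gompertz_scale)
    for gene in sorted(gene_effects):
        factor = float(gene_effects[gene])
        treated_p = gompertz_survival(days / factor, gompertz_shape, gompertz_scale)
        if n_scored <= 0:
            treated = control = (0.0,) * len(days)
        else:
            treated = tuple(rng.binomial(n_scored, p) / n_scored for p in treated_p)
            control = tuple(rng.binomial(n_scored, p) / n_scored for p in control_p)
        records[gene] = ThrashingRecord(
            gene=gene,
            survival_fraction=treated,
            control_fraction=control,
            n_scored=max(n_scored, 0),
        )
    return records


# ---------------------------------------------------------------------------
# whole-world generation

@dataclass(frozen=True)
class WorldConfig:
    """Knobs for one synthetic study world (defaults are the study conditions)."""

    n_nodes: int = 800
    model: str = "scale_free"
    model_params: Mapping[str, float] = field(default_factory=lambda: {"m": 3})
    core_size: int = 50
    density_boost: float = 4.0
    essential_fraction: float = 0.35
    core_essential_enrichment: float = 2.0
    orthology_coverage: float = 0.8
    paralog_rate: float = 0.1
    foreign_partner_sample: int = 300
    clone_fraction: float = 0.8
    n_effect_long: int = 12
    n_effect_short: int = 8
    effect_long: float = 1.3
    effect_short: float = 0.7
    n_animals: int = 90
    gompertz_shape: float = GOMPERTZ_SHAPE
    gompertz_scale: float = GOMPERTZ_SCALE
    censor_rate: float = 0.1
    n_scored: int = 30


@dataclass(frozen=True)
class SyntheticWorld:
    config: WorldConfig
    seed: int
    interactome: Interactome
    true_core: frozenset[str]
    essentiality: Mapping[str, bool]
    orthology: OrthologyMap
    foreign_partners: AnnotatedGeneSet          # foreign-species ids
    clones: AnnotatedGeneSet
    wln: LongevityNetwork
    candidates: CandidateSet                    # after clone filtering
    lifespan_effects: Mapping[str, float]       # screened gene -> factor
    effect_genes_long: frozenset[str]
    effect_genes_short: frozenset[str]
    lifespans: Mapping[str, SurvivalDataset]
    thrashing: Mapping[str, ThrashingRecord]


def gen_world(config: WorldConfig | None = None, seed: int = 42) -> SyntheticWorld:
    """Generate a complete study world; deterministic in (config, seed)."""
    cfg = config or WorldConfig()
    if cfg.core_size >= cfg.n_nodes:
        raise DataError("core_size must be smaller than n_nodes")
    s = _child_seeds(seed, 9)
    interactome = gen_interactome(
        cfg.n_nodes, cfg.model, seed=s[0], **dict(cfg.model_params)
    )
    interactome, core = plant_core_module(
        interactome, cfg.core_size, cfg.density_boost, seed=s[1]
    )
    essentiality = gen_annotations(
        interactome, cfg.essential_fraction, cfg.core_essential_enrichment,
        seed=s[2], core=core,
    )
    orthology = gen_orthology(
        sorted(interactome.nodes), cfg.orthology_coverage, cfg.paralog_rate, seed=s[3]
    )
    core_set = AnnotatedGeneSet(species="worm", genes=core, label="core LAGs")
    wln = build_longevity_network(interactome, core_set)

    # foreign-network partner set: biased toward neighbors of the planted
    # module so the two candidate sources overlap, plus unrelated genes
    rng = np.random.default_rng(s[4])
    neighborhood = sorted(
        set().union(*(interactome.neighbors(g) for g in core)) - core
    )
    others = sorted(interactome.nodes - set(neighborhood) - core)
    n_nb = min(len(neighborhood), int(0.6 * cfg.foreign_partner_sample))
    n_ot = min(len(others), cfg.foreign_partner_sample - n_nb)
    picked = (
        rng.choice(np.array(neighborhood), size=n_nb, replace=False).tolist()
        + rng.choice(np.array(others), size=n_ot, replace=False).tolist()
    )
    forward = orthology.forward()
    foreign_ids = frozenset().union(
        *(forward.get(g, frozenset()) for g in picked)
    ) if picked else frozenset()
    foreign_partners = AnnotatedGeneSet(
        species="human", genes=frozenset(foreign_ids), label="foreign network partners"
    )
    hln_orthologs, _ = map_gene_set(foreign_partners, orthology, direction="ba")

    essential_set = AnnotatedGeneSet(
        species="worm",
        genes=frozenset(g for g, v in essentiality.items() if v),
        label="essential",
    )
    known = AnnotatedGeneSet(species="worm", genes=core, label="known LAGs")
    selected = select_candidates(wln, hln_orthologs, known, essential_set)
    rng_clones = np.random.default_rng(s[5])
    clone_genes = frozenset(
        g for g in sorted(interactome.nodes) if rng_clones.random() < cfg.clone_fraction
    )
    clones = AnnotatedGeneSet(species="worm", genes=clone_genes, label="clone-available")
    candidates = apply_clone_availability(selected, clones)

    screened = sorted(candidates.candidates)
    n_eff = cfg.n_effect_long + cfg.n_effect_short
    if n_eff > len(screened):
        raise DataError(
            f"world too small: {len(screened)} screened genes < {n_eff} planted effects"
        )
    rng_eff = np.random.default_rng(s[6])
    chosen = rng_eff.choice(np.array(screened), size=n_eff, replace=False).tolist()
    longs = frozenset(chosen[: cfg.n_effect_long])
    shorts = frozenset(chosen[cfg.n_effect_long:])
    effects = {
        g: (cfg.effect_long if g in longs else cfg.effect_short if g in shorts else 1.0)
        for g in screened
    }
    lifespans = gen_lifespans(
        effects, cfg.n_animals, cfg.gompertz_shape, cfg.gompertz_scale,
        cfg.censor_rate, seed=s[7],
    )
    thrashing = gen_thrashing(
        effects, THRASHING_DAYS, cfg.n_scored, seed=s[8],
        gompertz_shape=cfg.gompertz_shape, gompertz_scale=cfg.gompertz_scale,
    )
    return SyntheticWorld(
        config=cfg, seed=seed, interactome=interactome, true_core=core,
        essentiality=essentiality, orthology=orthology,
        foreign_partners=foreign_partners, clones=clones, wln=wln,
        candidates=candidates,
        lifespan_effects=effects, effect_genes_long=longs,
        effect_genes_short=shorts, lifespans=lifespans, thrashing=thrashing,
    )


def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write every pipeline input file; byte-identical for identical worlds."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, lines: list[str]) -> None:
        p = out / name
        p.write_text("\n".join(lines) + "\n")
        paths[name] = p

    _write("edges.tsv", [f"{a}\t{b}" for a, b in sorted(
        tuple(sorted(e)) for e in world.interactome.edge_set())])
    _write("core.tsv", sorted(world.true_core))
    _write("known_lags.tsv", sorted(world.true_core))
    _write("essential.tsv", sorted(g for g, v in world.essentiality.items() if v))
    _write("clones.tsv", sorted(world.clones.genes))
    _write("orthology.tsv", [f"{a}\t{b}" for a, b in sorted(world.orthology.pairs)])
    _write("hln_partners.tsv", sorted(world.foreign_partners.genes))

    surv_lines = ["gene,group,time,event"]
    for gene in sorted(world.lifespans):
        ds = world.lifespans[gene]
        group = "control" if gene == "control" else "treated"
        for t, e in zip(ds.times, ds.events):
            surv_lines.append(f"{gene},{group},{t:.6f},{int(e)}")
    _write("survival.csv", surv_lines)

    thr_lines = ["gene,day,treated_alive,treated_total,control_alive,control_total"]
    for gene in sorted(world.thrashing):
        rec = world.thrashing[gene]
        for day, tf, cf in zip(THRASHING_DAYS, rec.survival_fraction, rec.control_fraction):
            thr_lines.append(
                f"{gene},{day:g},{round(tf * rec.n_scored)},{rec.n_scored},"
                f"{round(cf * rec.n_scored)},{rec.n_scored}"
            )
    _write("thrashing.csv", thr_lines)

    truth = {
        "seed": world.seed,
        "true_core": sorted(world.true_core),
        "effect_genes_long": sorted(world.effect_genes_long),
        "effect_genes_short": sorted(world.effect_genes_short),
        "screened": sorted(world.candidates.candidates),
        "config": {k: (dict(v) if isinstance(v, Mapping) else v)
                   for k, v in asdict(world.config).items()},
    }
    p = out / "truth.json"
    p.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    paths["truth.json"] = p
    return paths
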