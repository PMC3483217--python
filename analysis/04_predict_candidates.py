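"""Select candidate longevity genes from the two network sources.

A candidate must be a first-order partner in the native longevity network
or the native ortholog of a foreign-network partner, must not already be a
known longevity gene, must be essential, and must have an RNAi clone
available.  Writes the candidate table with per-gene provenance
(WLN_only / HLN_only / shared) and the full prediction report.
"""

from pathlib import Path

from longnet.pipeline import PipelineConfig, run_predict

WORLD = Path("results/world")
OUT = Path("results/predict")

config = PipelineConfig(
    edges=str(WORLD / "edges.tsv"),
    core=str(WORLD / "core.tsv"),
    orthology=str(WORLD / "orthology.tsv"),
    hln_partners=str(WORLD / "hln_partners.tsv"),
    essential=str(WORLD / "essential.tsv"),
    known_lags=str(WORLD / "known_lags.tsv"),
    clones=str(WORLD / "clones.tsv"),
    out_dir=str(OUT),
    n_permutations=999,
    seed=42,
)
report = run_predict(config)

funnel = report["selection_funnel"]
partition = report["partition"]
print(f"candidate pool (partners + orthologs): {funnel['pool']}")
print(f"after known-gene and essentiality filters: {funnel['after_filters']}")
print(f"after clone availability: {funnel['after_clones']}")
print(f"partition: {partition['WLN_only']} WLN-only, {partition['HLN_only']} "
      f"HLN-only, {partition['shared']} shared = {partition['total']} screened")
print(f"outputs in {OUT}/")
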